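import numpy as np
import pytest
from hypothesis import settings

from pcpkit.config import PipelineConfig, SimConfig

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

# pixel pitch used for snapshot-scale simulations: a 512 px frame then spans
# ~205 µm, a realistic co-culture field of view
SNAPSHOT_PX_NM = 400.0


@pytest.fixture(scope="session")
def snapshot_config() -> PipelineConfig:
    return PipelineConfig(pixel_size=SNAPSHOT_PX_NM)


@pytest.fixture(scope="session")
def snapshot_sim() -> SimConfig:
    return SimConfig(seed=3, pixel_size=SNAPSHOT_PX_NM, image_shape=(512, 512))


@pytest.fixture(scope="session")
def default_snapshot(snapshot_sim):
    """One rendered co-culture snapshot with ground truth, shared read-only."""
    from pcpkit.synthetic import PopulationParams, simulate_snapshot

    return simulate_snapshot(snapshot_sim, PopulationParams(n_cells=120))


@pytest.fixture(scope="session")
def analyzed_snapshot(default_snapshot, snapshot_config):
    """The default snapshot run through the full analysis pipeline."""
    from pcpkit.snapshot import SnapshotImage, analyze_snapshot

    img = SnapshotImage(default_snapshot.image,
                        pixel_size=default_snapshot.config.pixel_size)
    labels, cells, table, mask = analyze_snapshot(img, snapshot_config)
    return labels, cells, table, mask


def match_cells_to_truth(cells, truth):
    """Map detected cell ids to ground-truth ids via nucleus position."""
    return {
        r.cell_id: int(truth.label_map[int(round(r.nucleus_row)),
                                       int(round(r.nucleus_col))])
        for r in cells.itertuples()
    }


def interface_confusion(table, cells, truth):
    """(tp, fp, fn) of accumulating-interface detection against ground truth."""
    match = match_cells_to_truth(cells, truth)
    truth_rows = {(min(r.cell_a, r.cell_b), max(r.cell_a, r.cell_b)): r
                  for r in truth.interface_table.itertuples()}
    detected = {}
    for r in table.itertuples():
        a, b = match.get(r.cell_a, 0), match.get(r.cell_b, 0)
        if a and b:
            detected[(min(a, b), max(a, b))] = bool(r.accumulating)
    tp = fp = fn = 0
    for key, row in truth_rows.items():
        det = detected.get(key, False)
        if row.accumulating and det:
            tp += 1
        elif row.accumulating and not det:
            fn += 1
        elif det and not row.accumulating:
            fp += 1
    fp += sum(1 for key, det in detected.items()
              if det and key not in truth_rows)
    return tp, fp, fn
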