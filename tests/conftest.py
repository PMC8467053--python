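import numpy as np
import pytest

from lipidmsi.core_io import MSIDataset, ROIMask, SectionMeta
from lipidmsi.synthetic import GeneratorConfig, generate_study
from lipidmsi import pipeline


def make_section(
    intensities: np.ndarray,
    mz_axis: np.ndarray,
    labels=None,
    section_id: str = "S1",
    bio_sample: str = "B1",
    tech_rep: int = 1,
    arm: str = "control",
    width: int | None = None,
) -> MSIDataset:
    """Hand-built single-section dataset on a square-ish grid."""
    intensities = np.asarray(intensities, dtype=float)
    n = intensities.shape[0]
    w = width or int(np.ceil(np.sqrt(n)))
    coords = np.array([(i % w, i // w) for i in range(n)])
    roi = ROIMask()
    if labels is not None:
        for xy, lab in zip(coords, labels):
            roi[tuple(xy)] = lab
    else:
        for xy in coords:
            roi[tuple(xy)] = "tumor"
    meta = SectionMeta(section_id, bio_sample, tech_rep, arm)
    return MSIDataset(coords, meta, mz_axis=mz_axis, intensities=intensities, roi=roi)


@pytest.fixture(scope="session")
def small_study():
    """A reduced synthetic study shared across tests (24x24 grid, seed 7)."""
    cfg = GeneratorConfig(grid=(24, 24), n_intraday=3)
    sections, truth = generate_study(cfg, seed=7)
    return pipeline.normalize_study(sections), truth, cfg


@pytest.fixture(scope="session")
def small_master(small_study):
    sections, truth, _cfg = small_study
    master, audit = pipeline.masterlist_pipeline(sections, normalized=True)
    return master, audit
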