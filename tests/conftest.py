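import numpy as np
import pytest

from tampol.cell_model import CellRecord, CoreTable, MARKERS
from tampol.synthetic import SimConfig, generate_cohort


def make_cell(cell_id, core_id, x, y, phenotype="macrophage",
              compartment="stroma", **markers):
    intensity = {m: 1.0 for m in MARKERS}
    intensity.update(markers)
    return CellRecord(cell_id=cell_id, core_id=core_id, x_um=x, y_um=y,
                      phenotype=phenotype, compartment=compartment,
                      intensity=intensity)


def make_core(core_id, sample_id="S1", patient_id="P1", region="tumour_centre",
              qc="ok", area_epi=0.3, area_stroma=0.5, cells=()):
    return CoreTable(core_id=core_id, sample_id=sample_id, patient_id=patient_id,
                     region=region, qc=qc, area_epithelium_mm2=area_epi,
                     area_stroma_mm2=area_stroma, cells=list(cells))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A 4-patient synthetic cohort shared by slower tests (seed fixed)."""
    return generate_cohort(SimConfig(n_patients=4, seed=7))
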