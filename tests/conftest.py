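import numpy as np
import pandas as pd
import pytest

from lesionlink.normalize import ExpressionMatrix, rma
from lesionlink.synthetic_data import (EffectSpec, LesionKinetics, StudyDesign,
                                       generate_study)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def default_kinetics():
    return LesionKinetics()


@pytest.fixture(scope="session")
def noiseless_kinetics():
    return LesionKinetics(measurement_cv=0.0)


@pytest.fixture(scope="session")
def small_study():
    """One modest truth-labelled study shared by read-only tests."""
    design = StudyDesign(n_probesets=150)
    effects = EffectSpec(seed=12345, frac_treatment_de=0.1, frac_genotype_de=0.04,
                         frac_interaction_de=0.04, frac_lab_inconsistent=0.04,
                         frac_anchored=0.08)
    return generate_study(design, effects, LesionKinetics())


@pytest.fixture(scope="session")
def small_study_norm(small_study):
    mapping = small_study.annotation.set_index("probe_id")["probeset_id"]
    return rma(small_study.expression, mapping)


def make_balanced_sheet(n_per_cell: int = 3, timepoints=(6,)) -> pd.DataFrame:
    """2 sites x 2 genotypes x 2 treatments factorial sheet for unit tests."""
    rows = []
    i = 0
    for tp in timepoints:
        for site in ("siteA", "siteB"):
            for geno in ("wt", "ko"):
                for trt in ("MAM", "vehicle"):
                    for r in range(n_per_cell):
                        i += 1
                        rows.append({"sample_id": f"s{i:03d}", "site": site,
                                     "genotype": geno, "treatment": trt,
                                     "timepoint_h": tp, "tissue": "brain",
                                     "animal_id": f"a{i:03d}"})
    return pd.DataFrame(rows)


@pytest.fixture
def balanced_sheet():
    return make_balanced_sheet()
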