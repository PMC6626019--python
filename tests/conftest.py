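import numpy as np
import pytest

from glycoscan import (
    GeneratorConfig,
    ProfileHMM,
    calibrate_gumbel,
    generate_family_set,
    generate_proteome,
)


def peaked_model(
    consensus: str,
    peak: float = 0.96,
    accession: str = "PK00001",
    name: str = "PEAKED",
) -> ProfileHMM:
    """A sharply peaked profile emitting `consensus` with probability `peak`."""
    from glycoscan.profiles import AA_INDEX

    m = len(consensus)
    me = np.full((m, 20), (1.0 - peak) / 19.0)
    for k, sym in enumerate(consensus):
        me[k, AA_INDEX[sym]] = peak
    ie = np.full((m, 20), 1.0 / 20.0)
    tr = np.tile([0.94, 0.03, 0.03, 0.5, 0.5, 0.5, 0.5], (m, 1))
    model = ProfileHMM(
        accession=accession,
        name=name,
        match_emissions=me,
        insert_emissions=ie,
        transitions=tr,
    )
    model.validate()
    return model


@pytest.fixture(scope="session")
def small_study():
    """A small synthetic study: 10 families, 120 proteins, seed 7."""
    cfg = GeneratorConfig(n_proteins=120, seed=7)
    families = generate_family_set(cfg)
    proteins, truth = generate_proteome(cfg, families)
    return cfg, families, proteins, truth


@pytest.fixture()
def calibrated_peaked():
    model = peaked_model("ACDEFGHIKLMNPQRSTVWYACDEFGHIKL")
    calibrate_gumbel(model, n_samples=300, seed=11)
    return model
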