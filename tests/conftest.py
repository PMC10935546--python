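import pytest

from condstab.sequence_features import (
    PkaTable,
    SequenceRecord,
    count_ionizable_groups,
)
from condstab.solution_model import IonSpecies, SolutionCondition, salt_ions
from condstab.synthetic_data import (
    NoiseSpec,
    REFERENCE_SEQUENCE_SPEC,
    TRUE_PARAMETERS,
    generate_dgsat_dataset,
    generate_sequence,
)


@pytest.fixture(scope="session")
def pka() -> PkaTable:
    return PkaTable()


@pytest.fixture(scope="session")
def reference_sequence() -> SequenceRecord:
    """Synthetic reference chain: 32 positives, 36 acids, 14 FG/RG motifs."""
    return generate_sequence(REFERENCE_SEQUENCE_SPEC, seed=7, seq_id="N1")


@pytest.fixture(scope="session")
def reference_counts(reference_sequence):
    return count_ionizable_groups(reference_sequence)


@pytest.fixture(scope="session")
def saline_condition() -> SolutionCondition:
    """150 mM NaCl + 20 mM buffer background at pH 8."""
    return SolutionCondition(
        pH=8.0, T=295.15, ions=tuple(salt_ions("Na", 1, 150.0)),
        extra_ionic_strength=20.0,
    )


@pytest.fixture(scope="session")
def true_params():
    return TRUE_PARAMETERS


@pytest.fixture(scope="session")
def noiseless_dataset():
    ds, truth = generate_dgsat_dataset(noise=NoiseSpec(sigma_dg=0.0, seed=11))
    return ds, truth
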