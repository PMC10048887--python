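import pytest

from cypene.energetics import (
    Molecule,
    Site,
    SpeciesLabel,
    Stage,
    StationaryPoint,
    Stereopath,
)


@pytest.fixture
def beta_delta_label():
    return SpeciesLabel(
        molecule=Molecule.BETA_PINENE,
        site=Site.DELTA,
        stereopath=Stereopath.TRANS,
        multiplicity=2,
    )


def make_point(label, stage, g, **kwargs):
    return StationaryPoint(label=label, stage=stage, g=g, **kwargs)


@pytest.fixture
def simple_path_points(beta_delta_label):
    """A complete I→II→III→IV path with round free energies (Eh)."""
    return [
        make_point(beta_delta_label, Stage.REACTANT_COMPLEX, 0.0,
                   e_elec=0.0, h=0.0, g_uncorrected=0.0),
        make_point(beta_delta_label, Stage.ABSTRACTION_TS, 0.02,
                   e_elec=0.02, h=0.02, g_uncorrected=0.02),
        make_point(beta_delta_label, Stage.RADICAL, -0.01,
                   e_elec=-0.01, h=-0.01, g_uncorrected=-0.01),
        make_point(beta_delta_label, Stage.HYDROXYLATED, -0.08),
    ]
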