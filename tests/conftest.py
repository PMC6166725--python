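import pytest

from ppiscan import synthetic_data as sd

#: 60-residue synthetic unfolded substrate: hydrophilic flanks around one
#: hydrophobic stretch (25-33, LVAGPWLIV) with a proline-aromatic pair
#: P29-W30; P13 is a hydrophilic-region control proline.
DEMO_SEQ = "SNKEDQTSGS" "KDPEQNSTGD" "QSTALVAGPW" "LIVTDKEQSN" "GSDKEQTSNG" "DSKTEQNGSD"


@pytest.fixture(scope="session")
def demo_sequence():
    return DEMO_SEQ


@pytest.fixture(scope="session")
def coarse_scan_spec():
    """The study's endpoints at a 2 deg step: 88 models, fast to build."""
    return sd.PeptideScanSpec(
        n_residues=5, proline_index=3,
        start_omega=-174.0, end_omega=0.0, step=2.0, dwell=2.0,
        direction="clockwise",
    )


@pytest.fixture(scope="session")
def coarse_scan(coarse_scan_spec):
    return sd.generate_peptide_scan(coarse_scan_spec)


@pytest.fixture(scope="session")
def noiseless_titration(demo_sequence):
    spec = sd.TitrationSpec(
        sequence=demo_sequence, sites=[(25, 33, 0.9)], noise_sd=0.0, seed=11
    )
    return spec, sd.generate_titration(spec)
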