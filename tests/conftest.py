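import pytest

from sarpscout import fixtures


@pytest.fixture(scope="session")
def demo_truth():
    """The standard 3-cluster demo screen (seed 42), generated once."""
    return fixtures.demo_screen(seed=42)


@pytest.fixture(scope="session")
def demo_files(demo_truth, tmp_path_factory):
    """Demo screen written to disk as the readers consume it."""
    outdir = tmp_path_factory.mktemp("demo_fixture")
    return fixtures.write_fixture_files(demo_truth, outdir)


def naive_site_identity(site, consensus="GTCAGSS"):
    """Independent position-by-position identity oracle (single heptamer).

    Spells out IUPAC semantics by hand; N in the site matches nothing.
    """
    iupac = {
        "A": "A", "C": "C", "G": "G", "T": "T",
        "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
        "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
    }
    assert len(site) == len(consensus)
    matches = sum(1 for b, c in zip(site.upper(), consensus) if b in iupac[c])
    return matches / len(consensus)
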