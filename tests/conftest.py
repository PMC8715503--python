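import pytest

from cspmatch import Peak, PeakList, SyntheticSpec, generate_pair
from cspmatch.synthetic import make_swap_case


def make_peak(pid, h, het, res=None, label=None, nucleus="N15"):
    return Peak(
        peak_id=pid, shift_h=h, shift_het=het, het_nucleus=nucleus,
        residue_index=res, residue_label=label,
    )


@pytest.fixture
def three_peak_list():
    """Three assigned, well-separated amide peaks."""
    return PeakList(
        name="three",
        peaks=(
            make_peak("p1", 7.2, 112.0, res=5, label="G5"),
            make_peak("p2", 8.1, 118.5, res=6, label="A6"),
            make_peak("p3", 9.4, 127.0, res=7, label="L7"),
        ),
    )


@pytest.fixture
def swap_case():
    """The hand-verified planted case where Smart algorithms beat SD/RA."""
    return make_swap_case()


@pytest.fixture
def small_synthetic():
    """A modest default-condition synthetic pair (fast to match)."""
    spec = SyntheticSpec(n_residues=60, binding_site=(25, 31), seed=11)
    return generate_pair(spec)


@pytest.fixture
def write_csv(tmp_path):
    """Write csv text to a temp file and return its path."""
    def _write(text, name="peaks.csv"):
        path = tmp_path / name
        path.write_text(text)
        return path
    return _write


def random_cost_matrix(rng, n, m=None):
    m = n if m is None else m
    return rng.uniform(0.01, 2.0, size=(n, m))
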