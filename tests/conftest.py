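import pytest

from cistrodiff.motif_scan import scan_pwm
from cistrodiff.synthetic_data import SyntheticDesign, build_fixture, builtin_pwms


@pytest.fixture(scope="session")
def default_fixture():
    """The package's default study-condition fixture (built once per session)."""
    return build_fixture(SyntheticDesign(seed=1))


@pytest.fixture(scope="session")
def fixture_hitsets(default_fixture):
    """Genome-wide hits of every built-in motif on the default fixture.

    Planted motifs are exact consensi, so scanning uses the stringent
    relative threshold (0.9) at which only exact matches score.
    """
    pwms = builtin_pwms()
    return {
        m: scan_pwm(default_fixture.genome, p, 0.9) for m, p in pwms.items()
    }


@pytest.fixture(scope="session")
def small_design():
    """A miniature design for fast end-to-end and CLI tests."""
    return SyntheticDesign(
        seed=5,
        n_chroms=1,
        chrom_length=80_000,
        n_peaks=60,
        n_genes=60,
        n_up=6,
        n_down=6,
    )


def random_intervals(rng, n, n_chroms=3, max_pos=5000, max_len=120,
                     with_name=False, with_score=False, with_strand=False):
    """Random valid intervals for oracle tests."""
    from cistrodiff.genomic_io import GenomicInterval

    out = []
    for i in range(n):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        start = int(rng.integers(0, max_pos))
        end = start + int(rng.integers(1, max_len))
        out.append(
            GenomicInterval(
                chrom,
                start,
                end,
                name=f"iv{i}" if with_name else None,
                score=float(rng.integers(0, 1000)) if with_score else None,
                strand=("+", "-")[int(rng.integers(0, 2))] if with_strand else ".",
            )
        )
    return out
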