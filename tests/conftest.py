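import numpy as np
import pandas as pd
import pytest

from slrscan import GenotypeMatrix, SampleSheet, SimConfig, SlrSpec, simulate_cohort


def make_gm(codes, samples=None, chrom="chr1", start_pos=100, spacing=1000):
    """Tiny GenotypeMatrix from a loci x samples list of codes."""
    codes = np.asarray(codes, dtype=np.int8)
    n_loci, n_samples = codes.shape
    samples = samples or [f"S{i}" for i in range(n_samples)]
    loci = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": start_pos + spacing * np.arange(n_loci),
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypeMatrix(loci, samples, codes)


def make_sheet(sexes, samples=None, male_classes=None):
    samples = samples or [f"S{i}" for i in range(len(sexes))]
    frame = pd.DataFrame({"sample_id": samples, "sex": list(sexes)})
    if male_classes is not None:
        frame["male_class"] = male_classes
    return SampleSheet(frame)


def small_sim_config(seed=11, **overrides):
    """Desk-scale version of the default study conditions: same cohort and
    rates, 12 Mb genome with a 1 Mb XY SLR and a 200 kb hemizygous segment."""
    kwargs = dict(
        chrom_lengths={"chr2": 4_000_000, "chr6": 8_000_000},
        slr_specs=[
            SlrSpec("chr6", 3_000_000, 4_000_000, "XY_DIFFERENTIAL", snp_rate=2.0),
            SlrSpec("chr2", 1_000_000, 1_050_000, "XY_DIFFERENTIAL", snp_rate=1.0),
            SlrSpec("chr2", 1_050_000, 1_250_000, "Y_HEMIZYGOUS"),
        ],
        seed=seed,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    """One simulated cohort shared by read-only tests."""
    return simulate_cohort(small_sim_config())


@pytest.fixture(scope="session")
def clean_cohort():
    """Error-free, fully-called cohort (exact-recovery oracles)."""
    return simulate_cohort(
        small_sim_config(seed=13, genotype_error=0.0, missing_rate=0.0)
    )
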