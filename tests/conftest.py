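import numpy as np
import pandas as pd
import pytest

from qdaflux import synthetic_data as sd


@pytest.fixture(scope="session")
def demo_model():
    return sd.make_demo_model(seed=11, chrom_len=40_000, n_genes=15)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def orf_sites():
    """Ten well-separated GATC sites, all ORF class, on a 6-kb chromosome."""
    return sd.class_sites_table({"ORF": 10}, spacing=500, chrom="chrT")


def brute_force_fcut(sites: pd.DataFrame, frags: pd.DataFrame) -> pd.DataFrame:
    """Independent per-fragment enumeration oracle for fcut.

    Loops over every (site, fragment) pair and counts ends/coverage directly
    from interval arithmetic — no tracks, no difference arrays.
    """
    rows = []
    for site in sites.itertuples():
        s = int(site.start)
        nrA = nrG = nlT = nlC = covG = covC = 0
        for f in frags.itertuples():
            if f.chrom != site.chrom:
                continue
            last = f.end - 1
            if f.start <= s < f.end:
                covG += 1
            if f.start <= s + 3 < f.end:
                covC += 1
            if last == s:
                nrG += 1
            elif last == s + 1:
                nrA += 1
            if f.start == s + 2:
                nlT += 1
            elif f.start == s + 3:
                nlC += 1
        rows.append(
            {
                "chrom": site.chrom, "start": s,
                "n_right_A": nrA, "n_right_G": nrG, "n_left_T": nlT, "n_left_C": nlC,
                "cov_G": covG, "cov_C": covC,
                "fcut_right": (nrA + nrG) / covG if covG else np.nan,
                "fcut_left": (nlT + nlC) / covC if covC else np.nan,
            }
        )
    return pd.DataFrame(rows)
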