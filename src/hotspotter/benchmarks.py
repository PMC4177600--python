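"""Synthetic stand-in benchmark tables for the two alanine-scanning corpora.

The original residue-level tables (an ASEdb-derived training table of 316
alanine-mutated interface residues across 19 complexes, and a BID-derived
test table of 125 residues across 18 complexes) are distributed as
supplementary spreadsheets that cannot be redistributed here. These
generators emit *synthetic* tables with the same documented composition -
record counts, complex counts, and class sizes produced by the published
cutoffs (78 hotspots / 119 non-hotspots after ddG filtering; 38 strong /
87 other) - with ddG values and strength labels drawn from seeded
distributions on the appropriate side of each cutoff. They exercise the
labelling, joining and metric machinery; they carry no real mutagenesis data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# composition of the ASEdb-style training table
ASEDB_N_COMPLEXES = 19
ASEDB_N_HOTSPOT = 78       # ddG >= 2.0
ASEDB_N_NONHOTSPOT = 119   # ddG < 0.4
ASEDB_N_EXCLUDED = 119     # 0.4 <= ddG < 2.0; total 316

# composition of the BID-style test table
BID_N_COMPLEXES = 18
BID_N_STRONG = 38
BID_N_OTHER = 87           # intermediate/weak/insignificant; total 125

_AA = list("ACDEFGHIKLMNPQRSTVWY")


def _assign_complexes(n_records: int, n_complexes: int, prefix: str,
                      rng: np.random.Generator) -> list:
    ids = [f"{prefix}{k + 1:03d}" for k in range(n_complexes)]
    # every complex appears at least once; remainder assigned at random
    choices = ids * (n_records // n_complexes) + \
        list(rng.choice(ids, size=n_records - n_complexes * (n_records // n_complexes),
                        replace=False))
    rng.shuffle(choices)
    return choices


def make_asedb_like_table(seed: int = 0) -> pd.DataFrame:
    """Synthetic ddG table with the training corpus composition.

    78 records with ddG >= 2.0, 119 with ddG < 0.4 (including mildly
    stabilizing negatives) and 119 in the excluded band [0.4, 2.0),
    spread over 19 synthetic complex ids.
    """
    rng = np.random.default_rng(seed)
    n = ASEDB_N_HOTSPOT + ASEDB_N_NONHOTSPOT + ASEDB_N_EXCLUDED
    # ranges stop short of the cutoffs so rounding to 0.01 cannot cross them
    ddg = np.concatenate([
        rng.uniform(2.0, 6.5, size=ASEDB_N_HOTSPOT),
        rng.uniform(-1.0, 0.39, size=ASEDB_N_NONHOTSPOT),
        rng.uniform(0.4, 1.99, size=ASEDB_N_EXCLUDED),
    ])
    order = rng.permutation(n)
    df = pd.DataFrame({
        "complex_id": _assign_complexes(n, ASEDB_N_COMPLEXES, "SYNTRAIN", rng),
        "chain": rng.choice(list("AB"), size=n),
        "resnum": rng.integers(1, 250, size=n),
        "aa": rng.choice(_AA, size=n),
        "ddg": np.round(ddg[order], 2),
    })
    return df


def make_bid_like_table(seed: int = 0) -> pd.DataFrame:
    """Synthetic strength-labelled table with the test corpus composition:
    38 'strong' records and 87 others over 18 synthetic complex ids."""
    rng = np.random.default_rng(seed)
    n = BID_N_STRONG + BID_N_OTHER
    others = rng.choice(["intermediate", "weak", "insignificant"],
                        size=BID_N_OTHER)
    strength = np.concatenate([np.full(BID_N_STRONG, "strong"), others])
    rng.shuffle(strength)
    return pd.DataFrame({
        "complex_id": _assign_complexes(n, BID_N_COMPLEXES, "SYNTEST", rng),
        "chain": rng.choice(list("AB"), size=n),
        "resnum": rng.integers(1, 250, size=n),
        "aa": rng.choice(_AA, size=n),
        "strength": strength,
    })
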