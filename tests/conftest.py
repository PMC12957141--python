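import numpy as np
import pandas as pd
import pytest

from nichebreadth import trees
from nichebreadth.gower import TraitTable


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):1,C:2); — ultrametric, height 2."""
    return trees.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def deep_cherry_tree():
    """((A:1,B:1):9,C:10); — two congeners in a deep tree."""
    return trees.read_newick("((A:1,B:1):9,C:10);")


@pytest.fixture
def mixed_trait_table():
    """8 species x 6 mixed-type traits with a few missing values."""
    rng = np.random.default_rng(42)
    species = [f"s{i}" for i in range(8)]
    df = pd.DataFrame(
        {
            "mass": rng.lognormal(1.0, 0.8, 8),
            "longevity": rng.lognormal(2.0, 0.4, 8),
            "habitat_breadth": rng.integers(1, 6, 8),
            "trophic": rng.choice(["herbivore", "omnivore", "insectivore"], 8),
            "stratum": rng.choice(["ground", "scansorial", "arboreal"], 8),
            "hibernation": rng.choice(["yes", "no"], 8),
        },
        index=species,
    )
    df.loc["s2", "mass"] = np.nan
    df.loc["s5", "trophic"] = np.nan
    return TraitTable(
        data=df,
        types={
            "mass": "quantitative",
            "longevity": "quantitative",
            "habitat_breadth": "ordinal",
            "trophic": "categorical",
            "stratum": "categorical",
            "hibernation": "binary",
        },
    )


def gower_bruteforce(tt: TraitTable, ordinal_as_rank: bool = True) -> pd.DataFrame:
    """Independent double-loop Gower implementation (oracle)."""
    species = list(tt.data.index)
    cols = list(tt.data.columns)
    ranges = {}
    for c in cols:
        if tt.types[c] in ("quantitative", "ordinal"):
            x = tt.data[c].astype(float)
            ranges[c] = np.nanmax(x) - np.nanmin(x)
        else:
            obs = tt.data[c].dropna()
            ranges[c] = 1.0 if obs.nunique() > 1 else 0.0
    out = pd.DataFrame(0.0, index=species, columns=species)
    for i, a in enumerate(species):
        for j, b in enumerate(species):
            if i == j:
                continue
            num = den = 0.0
            for c in cols:
                va, vb = tt.data.loc[a, c], tt.data.loc[b, c]
                if pd.isna(va) or pd.isna(vb) or ranges[c] == 0:
                    continue
                w = tt.weights[c]
                if tt.types[c] in ("quantitative", "ordinal"):
                    s = abs(float(va) - float(vb)) / ranges[c]
                else:
                    s = 0.0 if va == vb else 1.0
                num += w * s
                den += w
            out.iloc[i, j] = num / den
    return out
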