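import numpy as np
import pandas as pd
import pytest

from rrgskit import popgen
from rrgskit.types import TrialDesign


@pytest.fixture(scope="session")
def small_founders():
    """30 inbred lines, 120 markers on 4 chromosomes."""
    return popgen.make_founders(30, 120, 4, 100.0, 0.1, 0.5, seed=11)


@pytest.fixture(scope="session")
def small_arch(small_founders):
    return popgen.make_architecture(
        small_founders.n_markers, 60, var_additive=4.0, dominance_ratio=0.5,
        intercept=90.0, seed=7,
    )


@pytest.fixture()
def balanced_table():
    """Balanced lines+hybrids trial for variance-component fixtures."""
    rng = np.random.default_rng(42)
    females = [f"F{i}" for i in range(8)]
    males = [f"M{i}" for i in range(3)]
    lines = females + males
    gca_f = dict(zip(females, rng.normal(scale=1.5, size=len(females))))
    gca_m = dict(zip(males, rng.normal(scale=0.8, size=len(males))))
    line_eff = dict(zip(lines, rng.normal(scale=2.0, size=len(lines))))
    rows = []
    for loc in ["L1", "L2", "L3", "L4"]:
        env_eff = rng.normal(scale=1.0)
        for block in (1, 2):
            blk = rng.normal(scale=0.5)
            for g in lines:
                rows.append(
                    dict(genotype_id=g, role="line", female_parent=None,
                         male_parent=None, location=loc, year=2019, block=block,
                         value=90 + line_eff[g] + env_eff + blk
                         + rng.normal(scale=1.0))
                )
            for f in females:
                for m in males:
                    sca = 0.3 * rng.normal()
                    rows.append(
                        dict(genotype_id=f"H_{f}_{m}", role="hybrid",
                             female_parent=f, male_parent=m, location=loc,
                             year=2019, block=block,
                             value=95 + gca_f[f] + gca_m[m] + sca + env_eff
                             + blk + rng.normal(scale=1.0))
                    )
    return pd.DataFrame(rows)


@pytest.fixture()
def stress_design():
    return TrialDesign(
        locations=["A", "B", "C", "D", "E", "F"],
        years=[2019],
        n_blocks=2,
        stress_locations=["E", "F"],
    )
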