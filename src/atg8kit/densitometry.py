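"""Western-blot densitometry: tubulin normalization, autophagic flux, tests.

The flux statistic quantifies autophagosome turnover from the lipidated
(form II) band of an ATG8 protein: BafA1 blocks lysosomal fusion, so the
BafA1-induced excess of tubulin-normalized lipidated signal over the
untreated lane estimates throughput,

    flux_r = (I_lip / I_tub)_{BafA1, r} - (I_lip / I_tub)_{no BafA1, r}

paired by replicate r (lanes of one membrane).  Group comparisons of flux
use Kruskal-Wallis with Benjamini-Hochberg-adjusted pairwise post-hocs;
normalized band intensities use a two-factor ANOVA
(treatment x protein, Type II sums of squares).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "REQUIRED_COLUMNS",
    "FluxResult",
    "validate_table",
    "normalize",
    "flux",
    "flux_table",
    "bh_adjust",
    "test_flux",
    "test_factorial",
]

REQUIRED_COLUMNS = ("protein", "treatment", "bafA1", "replicate", "band",
                    "intensity", "tubulin_intensity")
CONTROL_TREATMENT = "Ctrl"
BANDS = ("lipidated", "unlipidated", "total")


@dataclass
class FluxResult:
    protein: str
    treatment: str
    replicates: list[int]
    values: np.ndarray
    mean: float
    sd: float


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    t = table.copy()
    t["bafA1"] = t["bafA1"].astype(bool)
    if (t["tubulin_intensity"] <= 0).any():
        raise ValueError("tubulin_intensity must be > 0")
    if (t["intensity"] < 0).any():
        raise ValueError("intensity must be >= 0")
    bad = set(t["band"]) - set(BANDS)
    if bad:
        raise ValueError(f"unknown band labels: {sorted(bad)}")
    key = ["protein", "treatment", "bafA1", "replicate", "band"]
    if t.duplicated(key).any():
        raise ValueError("duplicate (protein, treatment, bafA1, replicate, band) rows")
    return t


def normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Tubulin-normalize and scale to the control mean.

    Each intensity becomes (I/I_tub) divided by the mean tubulin-normalized
    ratio of the control rows (treatment 'Ctrl', no BafA1) of the same
    (protein, band); the control mean maps to 1.  The returned table has
    tubulin_intensity 1, which makes the operation idempotent.
    """
    t = validate_table(table)
    ratio = t["intensity"] / t["tubulin_intensity"]
    t = t.assign(_ratio=ratio)
    out = []
    for (protein, band), grp in t.groupby(["protein", "band"], sort=False):
        ctrl = grp[(grp["treatment"] == CONTROL_TREATMENT) & (~grp["bafA1"])]
        if ctrl.empty:
            raise ValueError(f"missing control rows for ({protein}, {band})")
        denom = float(ctrl["_ratio"].mean())
        if denom == 0:
            raise ValueError(f"zero control mean for ({protein}, {band})")
        g = grp.copy()
        g["intensity"] = g["_ratio"] / denom
        g["tubulin_intensity"] = 1.0
        out.append(g.drop(columns="_ratio"))
    return pd.concat(out).sort_index()


def flux(table: pd.DataFrame, protein: str, treatment: str) -> FluxResult:
    """Per-replicate BafA1-minus-control difference of lipidated/tubulin ratios."""
    t = validate_table(table)
    rows = t[(t["protein"] == protein) & (t["treatment"] == treatment)
             & (t["band"] == "lipidated")]
    if rows.empty:
        raise ValueError(f"missing lipidated band for ({protein}, {treatment})")
    with_baf = rows[rows["bafA1"]].set_index("replicate")
    without = rows[~rows["bafA1"]].set_index("replicate")
    if set(with_baf.index) != set(without.index):
        raise ValueError(
            f"unpaired replicates for ({protein}, {treatment}): "
            f"with BafA1 {sorted(with_baf.index)}, without {sorted(without.index)}")
    if with_baf.empty:
        raise ValueError(f"no BafA1 lanes for ({protein}, {treatment})")
    reps = sorted(with_baf.index)
    r_with = (with_baf["intensity"] / with_baf["tubulin_intensity"]).loc[reps]
    r_without = (without["intensity"] / without["tubulin_intensity"]).loc[reps]
    values = (r_with - r_without).to_numpy(dtype=float)
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return FluxResult(protein, treatment, list(reps), values, float(values.mean()), sd)


def flux_table(table: pd.DataFrame) -> pd.DataFrame:
    """Flux for every (protein, treatment) with lipidated lanes; tidy frame."""
    t = validate_table(table)
    lip = t[t["band"] == "lipidated"]
    rows = []
    for (protein, treatment), _ in lip.groupby(["protein", "treatment"], sort=True):
        fr = flux(t, protein, treatment)
        for rep, v in zip(fr.replicates, fr.values):
            rows.append({"protein": protein, "treatment": treatment,
                         "replicate": rep, "flux": v})
    return pd.DataFrame(rows)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _kruskal(groups: list[np.ndarray]) -> tuple[float, float]:
    flat = np.concatenate(groups)
    if np.all(flat == flat[0]):  # scipy rejects the all-tied degenerate case
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def test_flux(flux_by_group: dict[str, np.ndarray],
              control: str = CONTROL_TREATMENT, alpha: float = 0.05) -> dict:
    """Kruskal-Wallis across treatments plus BH-adjusted post-hocs vs control.

    Post-hoc comparisons are two-sided Mann-Whitney tests of each treatment
    against the control group.
    """
    if len(flux_by_group) < 2:
        raise ValueError("need at least two groups")
    groups = {k: np.asarray(v, dtype=float) for k, v in flux_by_group.items()}
    for k, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} has fewer than 2 replicates")
    h, p = _kruskal(list(groups.values()))
    posthoc = []
    if control in groups:
        others = [k for k in groups if k != control]
        raw = []
        for k in others:
            if np.all(groups[k] == groups[k][0]) and np.all(groups[control] == groups[k][0]):
                raw.append(1.0)
            else:
                raw.append(float(stats.mannwhitneyu(
                    groups[k], groups[control], alternative="two-sided").pvalue))
        adj = bh_adjust(raw) if raw else np.array([])
        posthoc = [{"group": k, "p_raw": pr, "p_adjusted": pa,
                    "significant": bool(pa <= alpha)}
                   for k, pr, pa in zip(others, raw, adj)]
    return {"H": h, "p": p, "significant": bool(p <= alpha), "posthoc": posthoc}


def _stars(p: float) -> str:
    return "***" if p <= 0.001 else "**" if p <= 0.01 else "*" if p <= 0.05 else ""


def test_factorial(values: pd.DataFrame, *, response: str = "intensity",
                   factor1: str = "treatment", factor2: str = "protein",
                   control: str = CONTROL_TREATMENT) -> dict:
    """Two-factor ANOVA (Type II SS) with BH-adjusted contrasts vs control.

    ``values`` holds one row per replicate with the response and both factor
    columns.  Contrasts compare each non-control level of factor1 with the
    control within each level of factor2 (Welch t-tests), BH-adjusted as one
    family; stars follow the 0.05/0.01/0.001 convention.
    """
    for col in (response, factor1, factor2):
        if col not in values.columns:
            raise ValueError(f"missing column {col!r}")
    counts = values.groupby([factor1, factor2], sort=False).size()
    if (counts < 2).any():
        raise ValueError("every factor cell needs >= 2 replicates")
    df = values.rename(columns={response: "_y", factor1: "_f1", factor2: "_f2"})
    model = ols("_y ~ C(_f1) * C(_f2)", data=df).fit()
    y = df["_y"].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        # zero residual and zero effect variance: F undefined, report null
        effects = {name: {"F": 0.0, "p": 1.0, "stars": ""}
                   for name in (factor1, factor2, f"{factor1}:{factor2}")}
    else:
        tab = anova_lm(model, typ=2)
        key = {f"C(_f1)": factor1, f"C(_f2)": factor2,
               "C(_f1):C(_f2)": f"{factor1}:{factor2}"}
        resid_ss = float(tab.loc["Residual", "sum_sq"])
        scale = float(np.sum((y - y.mean()) ** 2))
        effects = {}
        for raw_name, name in key.items():
            ss = float(tab.loc[raw_name, "sum_sq"])
            if ss <= 1e-12 * max(scale, 1.0):
                f, p = 0.0, 1.0  # no effect variance at all
            elif resid_ss <= 1e-12 * max(scale, 1.0):
                f, p = float("inf"), 0.0  # exact effect, zero noise
            else:
                f = float(tab.loc[raw_name, "F"])
                p = float(tab.loc[raw_name, "PR(>F)"])
            effects[name] = {"F": f, "p": p, "stars": _stars(p)}
    contrasts = []
    raw_p = []
    for lvl2, sub in values.groupby(factor2, sort=True):
        ctrl_vals = sub.loc[sub[factor1] == control, response].to_numpy(dtype=float)
        if ctrl_vals.size == 0:
            continue
        for lvl1 in sorted(set(sub[factor1]) - {control}):
            v = sub.loc[sub[factor1] == lvl1, response].to_numpy(dtype=float)
            if v.std() == 0 and ctrl_vals.std() == 0:
                pr = 1.0 if v.mean() == ctrl_vals.mean() else 0.0
            else:
                pr = float(stats.ttest_ind(v, ctrl_vals, equal_var=False).pvalue)
            contrasts.append({"factor2": lvl2, "level": lvl1})
            raw_p.append(pr)
    adj = bh_adjust(raw_p) if raw_p else np.array([])
    for c, pr, pa in zip(contrasts, raw_p, adj):
        c.update(p_raw=pr, p_adjusted=float(pa), stars=_stars(float(pa)))
    return {"effects": effects, "contrasts": contrasts}


# these are statistical-test operations, not pytest cases
test_flux.__test__ = False
test_factorial.__test__ = False
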