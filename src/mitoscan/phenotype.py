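"""OxPhos phenotype stage: residualization, ANCOVA with Tukey–Kramer, regression.

State-3 respiration (ADP- and substrate-stimulated mitochondrial oxygen
consumption, pmol O2 s^-1 ml^-1 per ng DNA) is first residualized on
nuisance covariates (body mass continuous, acclimation and assay
temperature categorical, 3-population admixture fraction continuous).
Two tests follow: an ANCOVA with the four-way mito-nuclear group as the
main effect (type-II sums of squares for the unbalanced design,
Tukey–Kramer pairwise comparisons on covariate-adjusted group means)
and an OLS regression of the residuals on the southern-ancestry
fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.anova import anova_lm

logger = logging.getLogger(__name__)

__all__ = ["AssocResult", "residualize", "ancova_groups", "regress_ancestry"]

DEFAULT_COVARIATES = ("mass_g", "acclim_C", "assay_C", "admix")
_CATEGORICAL = {"acclim_C", "assay_C"}


@dataclass
class AssocResult:
    anova: pd.DataFrame | None = None
    tukey: pd.DataFrame | None = None
    letters: dict = field(default_factory=dict)
    slope: float = float("nan")
    slope_se: float = float("nan")
    r2: float = float("nan")
    p_value: float = float("nan")
    n_used: int = 0


def _covariate_terms(covariates) -> list[str]:
    return [f"C({c})" if c in _CATEGORICAL else c for c in covariates]


def _complete(table: pd.DataFrame, cols) -> pd.DataFrame:
    before = len(table)
    out = table.dropna(subset=list(cols))
    if len(out) < before:
        logger.warning("dropped %d rows with incomplete covariates", before - len(out))
    return out


def residualize(
    phenotype: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    response: str = "state3_rate",
) -> pd.Series:
    """OLS residuals of the phenotype on the covariate design.

    Returns residuals indexed by ``sample_id``.  A rank-deficient
    design raises, naming the offending columns.
    """
    covariates = [c for c in covariates if c in phenotype.columns]
    data = _complete(phenotype, [response, *covariates])
    formula = f"{response} ~ " + " + ".join(_covariate_terms(covariates) or ["1"])
    model = smf.ols(formula, data=data)
    X = model.exog
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient covariate design ({rank} < {X.shape[1]}): "
            f"check columns {model.exog_names}"
        )
    fit = model.fit()
    return pd.Series(fit.resid.to_numpy(), index=data["sample_id"], name="state3_resid")


def _tukey_kramer(
    means: np.ndarray, cov: np.ndarray, names: list, df_resid: float
) -> pd.DataFrame:
    """Pairwise Tukey–Kramer comparisons of covariate-adjusted means.

    The studentized-range statistic is q = |diff| · sqrt(2) / se(diff);
    adjusted p comes from the studentized range distribution with k
    groups and the model's residual df.
    """
    k = len(names)
    rows = []
    for i, j in combinations(range(k), 2):
        diff = means[i] - means[j]
        se = np.sqrt(cov[i, i] + cov[j, j] - 2.0 * cov[i, j])
        q = np.abs(diff) * np.sqrt(2.0) / se
        p_adj = float(sps.studentized_range.sf(q, k, df_resid))
        p_raw = 2.0 * float(sps.t.sf(np.abs(diff) / se, df_resid))
        rows.append((names[i], names[j], diff, se, q, p_raw, min(p_adj, 1.0)))
    return pd.DataFrame(
        rows, columns=["group_a", "group_b", "diff", "se", "q_stat", "p_raw", "p_adj"]
    )


def _letter_display(names: list, means: np.ndarray, tukey: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Compact letter display: groups sharing a letter are not significantly different."""
    order = np.argsort(-means)
    sorted_names = [names[i] for i in order]
    sig = {
        frozenset((r.group_a, r.group_b)): r.p_adj < alpha for r in tukey.itertuples()
    }
    blocks = []
    for i in range(len(sorted_names)):
        j = i
        while j + 1 < len(sorted_names) and not sig.get(
            frozenset((sorted_names[i], sorted_names[j + 1])), False
        ):
            j += 1
        block = set(sorted_names[i : j + 1])
        if not any(block <= b for b in blocks):
            blocks.append(block)
    letters = {name: "" for name in names}
    for letter, block in zip("abcdefghij", blocks):
        for name in block:
            letters[name] += letter
    return letters


def ancova_groups(
    phenotype: pd.DataFrame,
    groups: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    response: str = "state3_rate",
    alpha: float = 0.05,
) -> AssocResult:
    """ANCOVA with the mito-nuclear group as main effect.

    ``groups`` carries ``sample_id`` and ``group``.  Groups with fewer
    than two members are excluded (warned).  Reports the type-II ANOVA
    table, Tukey–Kramer pairwise comparisons on adjusted means, and a
    compact letter display at ``alpha``.
    """
    covariates = [c for c in covariates if c in phenotype.columns]
    data = phenotype.merge(groups[["sample_id", "group"]], on="sample_id")
    data = _complete(data, [response, "group", *covariates])
    sizes = data["group"].value_counts()
    small = sizes[sizes < 2].index
    if len(small):
        logger.warning("excluding groups with <2 members: %s", list(small))
        data = data[~data["group"].isin(small)]
    if data["group"].nunique() < 2:
        raise ValueError("need at least two non-empty groups")

    terms = ["C(group)"] + _covariate_terms(covariates)
    fit = smf.ols(f"{response} ~ " + " + ".join(terms), data=data).fit()
    anova = anova_lm(fit, typ=2)

    # covariate-adjusted group means: treatment coefficients shifted to
    # the prediction at covariate means (constant offset cancels in
    # pairwise differences, but makes the reported means interpretable)
    names = sorted(data["group"].unique())
    coef_idx = []
    params = fit.params
    base = names[0]
    for name in names:
        label = f"C(group)[T.{name}]"
        coef_idx.append(label if label in params.index else None)
    eff = np.array([0.0 if c is None else params[c] for c in coef_idx])
    cov_full = fit.cov_params()
    cov = np.zeros((len(names), len(names)))
    for a, ca in enumerate(coef_idx):
        for b, cb in enumerate(coef_idx):
            if ca is not None and cb is not None:
                cov[a, b] = cov_full.loc[ca, cb]
    tukey = _tukey_kramer(eff, cov, names, fit.df_resid)
    letters = _letter_display(names, eff, tukey, alpha=alpha)

    res = AssocResult(
        anova=anova,
        tukey=tukey,
        letters=letters,
        r2=float(fit.rsquared),
        p_value=float(anova.loc["C(group)", "PR(>F)"]),
        n_used=int(fit.nobs),
    )
    return res


def regress_ancestry(
    phenotype: pd.DataFrame,
    q_south: pd.Series | pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    response: str = "state3_rate",
) -> AssocResult:
    """Partial regression of the phenotype on the southern-ancestry fraction.

    Both the phenotype and the predictor are residualized on the same
    covariate design, so by the Frisch–Waugh–Lovell theorem the slope
    equals the ancestry coefficient of the full joint model.
    """
    if isinstance(q_south, pd.DataFrame):
        q_south = q_south.set_index("sample_id")["q_south"]
    q_south = q_south.rename("q_south")
    merged = phenotype.merge(q_south, left_on="sample_id", right_index=True)
    q_all = merged["q_south"].to_numpy(dtype=float)
    if np.nanmin(q_all) < 0 or np.nanmax(q_all) > 1:
        raise ValueError("q_south must lie in [0, 1]")
    resid_y = residualize(merged, covariates=covariates, response=response)
    resid_q = residualize(merged, covariates=covariates, response="q_south")
    joined = pd.concat(
        [resid_y, resid_q.rename("q_resid")], axis=1, join="inner"
    ).dropna()
    q = joined["q_resid"].to_numpy()
    if np.allclose(q, q[0]):
        raise ValueError("q_south is constant: no variance in the predictor")
    X = sm.add_constant(q)
    fit = sm.OLS(joined["state3_resid"].to_numpy(), X).fit()
    return AssocResult(
        slope=float(fit.params[1]),
        slope_se=float(fit.bse[1]),
        r2=float(fit.rsquared),
        p_value=float(fit.pvalues[1]),
        n_used=int(fit.nobs),
    )
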