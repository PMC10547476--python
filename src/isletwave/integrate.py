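"""Phenotype-proteome integration.

Animal-level waveform/spectral parameters and protein abundances are
Z-scored (sample SD, n-1), correlated pairwise-complete (Pearson), and
proteins whose |r| reaches 0.5 against three or more of the six focus
parameters are flagged as candidate regulators.  Strain/sex term-effect
statistics (least-squares fits with a composite strain "signal" F test)
summarise how strongly genetics drives each trait.

Z-score: z = (x - mu) / sigma with mu/sigma over all animals for the trait
(pooled sexes).  When the parameter animals and protein animals differ
(separate cohorts), alignment falls back to strain-by-sex group means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_FOCUS",
    "zscore",
    "zscore_frame",
    "normal_scores",
    "pearson",
    "correlate_matrix",
    "flag_candidates",
    "term_effects",
]

#: The six focus parameters most strongly tied to insulin secretion:
#: basal average Ca2+ plus the 8G active/pulse/silent durations and the
#: amino-acid and incretin-condition silent durations.
DEFAULT_FOCUS = (
    "2G_avg",
    "8G_active_min",
    "8G_pulse_min",
    "8G_silent_min",
    "8G_QLA_silent_min",
    "8G_QLA_GIP_silent_min",
)

_META_COLS = ("strain", "sex", "animal")


def zscore(column) -> pd.Series | np.ndarray:
    """Standardize a trait column: z = (x - mu)/sigma, sample SD (n-1).

    Missing values stay missing.  A constant column cannot be scaled; it is
    returned as all-missing with a warning so downstream correlation skips
    it.
    """
    is_series = isinstance(column, pd.Series)
    x = column.astype(float) if is_series else np.asarray(column, dtype=float)
    vals = x.to_numpy() if is_series else x
    ok = np.isfinite(vals)
    if ok.sum() < 2:
        raise ValueError("z-score needs at least two non-missing values")
    mu = vals[ok].mean()
    sd = vals[ok].std(ddof=1)
    if sd == 0:
        warnings.warn("constant column skipped in z-scoring", stacklevel=2)
        out = np.full_like(vals, np.nan)
    else:
        out = (vals - mu) / sd
    return pd.Series(out, index=x.index, name=x.name) if is_series else out


def zscore_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Z-score every trait column of a matrix, passing metadata through."""
    out = df.copy()
    for col in df.columns:
        if col in _META_COLS:
            continue
        out[col] = zscore(df[col])
    return out


def normal_scores(column) -> pd.Series | np.ndarray:
    """Rank-based inverse normal transform preserving mean and variance.

    Ranks (ties sharing the average rank) map to normal quantiles at
    r/(n+1), which are then rescaled to the input's sample mean and
    variance.  Strictly monotone in the input.
    """
    is_series = isinstance(column, pd.Series)
    vals = column.to_numpy(dtype=float) if is_series else np.asarray(column, dtype=float)
    ok = np.isfinite(vals)
    n = int(ok.sum())
    if n < 3:
        raise ValueError("normal scores need at least three non-missing values")
    ranks = stats.rankdata(vals[ok], method="average")
    q = stats.norm.ppf(ranks / (n + 1))
    qs = q.std(ddof=1)
    target_mu = vals[ok].mean()
    target_sd = vals[ok].std(ddof=1)
    scaled = q if qs == 0 else (q - q.mean()) / qs
    out = np.full_like(vals, np.nan)
    out[ok] = target_mu + target_sd * scaled
    return pd.Series(out, index=column.index, name=column.name) if is_series else out


def pearson(x, y) -> tuple[float, int]:
    """Pairwise-complete Pearson correlation; returns (r, n_used).

    r is missing when fewer than three complete pairs remain or either
    argument is constant on the complete set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        return float("nan"), n
    xs, ys = x[ok], y[ok]
    sx, sy = xs.std(), ys.std()
    if sx == 0 or sy == 0:
        return float("nan"), n
    r = float(((xs - xs.mean()) * (ys - ys.mean())).sum() / (n * sx * sy))
    return float(np.clip(r, -1.0, 1.0)), n


def _group_means(df: pd.DataFrame) -> pd.DataFrame:
    if not {"strain", "sex"}.issubset(df.columns):
        raise ValueError("group alignment needs 'strain' and 'sex' columns")
    traits = [c for c in df.columns if c not in _META_COLS]
    g = df.groupby(["strain", "sex"], sort=True)[traits].mean()
    g.index = [f"{s}_{x}" for s, x in g.index]
    return g


def correlate_matrix(
    params: pd.DataFrame,
    proteins: pd.DataFrame,
    align: str = "animal",
    scope: list[str] | None = None,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """All parameter x protein Pearson correlations on Z-scored columns.

    ``align='animal'`` joins the matrices on their (animal) index;
    ``align='group'`` first collapses both to strain-by-sex means, the rule
    used when the two experiments measured different mice.  ``scope``
    restricts to a strain subset before anything else.  Returns a long
    table (parameter, protein, r, n_used).
    """
    if align not in ("animal", "group"):
        raise ValueError("align must be 'animal' or 'group'")
    if scope is not None:
        if "strain" not in params.columns or "strain" not in proteins.columns:
            raise ValueError("scope restriction needs 'strain' columns")
        params = params[params["strain"].isin(scope)]
        proteins = proteins[proteins["strain"].isin(scope)]
    if align == "group":
        params, proteins = _group_means(params), _group_means(proteins)
    shared = params.index.intersection(proteins.index)
    if shared.empty:
        raise ValueError("no shared animal/group keys between the matrices")
    p_cols = [c for c in params.columns if c not in _META_COLS]
    q_cols = [c for c in proteins.columns if c not in _META_COLS]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns become all-NaN
        pz = zscore_frame(params.loc[shared, p_cols])
        qz = zscore_frame(proteins.loc[shared, q_cols])
    rows = []
    for par in p_cols:
        xv = pz[par].to_numpy()
        for prot in q_cols:
            r, n = pearson(xv, qz[prot].to_numpy())
            if n < min_pairs:
                r = float("nan")
            rows.append((par, prot, r, n))
    return pd.DataFrame(rows, columns=["parameter", "protein", "r", "n_used"])


@dataclass
class CandidateFlag:
    protein_id: str
    n_high: int
    flagged: bool


def flag_candidates(
    result: pd.DataFrame,
    focus: tuple[str, ...] = DEFAULT_FOCUS,
    threshold: float = 0.5,
    min_params: int = 3,
) -> pd.DataFrame:
    """Flag proteins with |r| >= threshold on >= min_params focus parameters.

    ``result`` is the long table from :func:`correlate_matrix`.  Returns a
    per-protein table (protein, n_high, flagged).  Unknown focus parameter
    ids are a configuration error.
    """
    have = set(result["parameter"].unique())
    missing = [f for f in focus if f not in have]
    if missing:
        raise ValueError(f"focus parameters not in correlation table: {missing}")
    sub = result[result["parameter"].isin(focus)]
    hits = (
        sub.assign(high=sub["r"].abs() >= threshold)
        .groupby("protein", sort=True)["high"]
        .sum()
        .astype(int)
    )
    out = hits.rename("n_high").reset_index()
    out["flagged"] = out["n_high"] >= min_params
    return out


def term_effects(
    values,
    strain,
    sex,
    trait_id: str = "",
) -> pd.DataFrame:
    """Strain/sex least-squares decomposition of one animal-level trait.

    Fits trait ~ strain + sex + strain:sex and reports, per term, the
    effect size sqrt(term mean square)/raw SD and the partial (type II)
    F-test p-value, plus a composite 'signal' row: the joint F test of all
    strain-involving terms against the sex-only model.  Terms that a
    rank-deficient design cannot estimate are reported missing.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = pd.DataFrame(
        {"y": np.asarray(values, dtype=float), "strain": np.asarray(strain), "sex": np.asarray(sex)}
    ).dropna()
    if df["strain"].nunique() < 2:
        raise ValueError("term effects need at least two strains")
    raw_sd = df["y"].std(ddof=1)
    rows = []
    full = smf.ols("y ~ C(strain) * C(sex)", data=df).fit()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            an = anova_lm(full, typ=2)
    except Exception:
        an = None
    term_map = {"C(strain)": "strain", "C(sex)": "sex", "C(strain):C(sex)": "strain:sex"}
    for key, name in term_map.items():
        if an is not None and key in an.index and np.isfinite(an.loc[key, "F"]):
            ms = an.loc[key, "sum_sq"] / max(an.loc[key, "df"], 1)
            ratio = float(np.sqrt(max(ms, 0.0)) / raw_sd) if raw_sd > 0 else float("nan")
            p = float(an.loc[key, "PR(>F)"])
        else:
            ratio, p = float("nan"), float("nan")
        rows.append((trait_id, name, ratio, p))
    # composite strain signal: joint F of strain + strain:sex vs sex-only
    try:
        reduced = smf.ols("y ~ C(sex)", data=df).fit()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cmp_ = anova_lm(reduced, full)
        f_p = float(cmp_["Pr(>F)"].iloc[1])
        extra_ss = float(cmp_["ss_diff"].iloc[1])
        extra_df = float(cmp_["df_diff"].iloc[1])
        ms = extra_ss / max(extra_df, 1.0)
        ratio = float(np.sqrt(max(ms, 0.0)) / raw_sd) if raw_sd > 0 else float("nan")
    except Exception:
        f_p, ratio = float("nan"), float("nan")
    rows.append((trait_id, "signal", ratio, f_p))
    out = pd.DataFrame(rows, columns=["trait_id", "term", "effect_sd_ratio", "p_value"])
    out["neg_log10_p"] = -np.log10(out["p_value"].clip(lower=np.finfo(float).tiny))
    return out
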