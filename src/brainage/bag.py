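"""Brain-age-gap (BAG) computation and group/continuous-skill inference.

BAG = true age - predicted age; positive values mean the model reads
the brain as younger than it is (the signature the maturational-lag
hypothesis predicts for poor readers). Group inference uses a
mixed-design repeated-measures ANCOVA: the ROI-set model is the
within-subject factor; reading group, true age, their interaction, and
nuisance covariates are between-subject terms. Because predictions
compress the age range, BAG correlates with true age even for unbiased
models, which is why age is always a covariate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
import statsmodels.formula.api as smf

AGE_BIN_EDGES = (6.0, 8.0, 9.5, 11.0, 13.0, 15.0, 21.0)
DEFAULT_COVARIATES = ("gender", "ses", "piq", "handedness")


@dataclass
class AncovaResult:
    effect: str
    F: float
    df1: float
    df2: float
    p: float
    partial_eta_sq: float
    correction: str = "none"


def compute_bag(true_age, predicted_age):
    """BAG in years: true - predicted (positive = underestimation)."""
    true_age = np.asarray(true_age, dtype=float)
    predicted_age = np.asarray(predicted_age, dtype=float)
    if not (np.all(np.isfinite(true_age)) and np.all(np.isfinite(predicted_age))):
        raise ValueError("ages must be finite")
    out = true_age - predicted_age
    return float(out) if out.ndim == 0 else out


def assign_age_bin(age):
    """Developmental age bin 1..6 for ages in [6, 21].

    Bins are left-closed, right-open — [6,8), [8,9.5), [9.5,11),
    [11,13), [13,15) — with the top bin [15,21] closed above, so a
    boundary age belongs to the higher bin.
    """
    a = np.asarray(age, dtype=float)
    if np.any(a < AGE_BIN_EDGES[0]) or np.any(a > AGE_BIN_EDGES[-1]):
        raise ValueError("age outside the 6-21 year range")
    bins = np.digitize(a, AGE_BIN_EDGES[1:-1], right=False) + 1
    return int(bins) if bins.ndim == 0 else bins.astype(int)


def build_bag_table(cohort: pd.DataFrame,
                    predictions: dict[str, np.ndarray]) -> pd.DataFrame:
    """Long table: one row per participant x model, BAG joined to phenotype.

    ``predictions`` maps a model label (e.g. ``"400-ROI"``) to the
    per-participant averaged rescaled predicted ages, aligned with the
    cohort rows.
    """
    frames = []
    for label, pred in predictions.items():
        pred = np.asarray(pred, dtype=float)
        if pred.shape[0] != len(cohort):
            raise ValueError(f"predictions for {label!r} do not match the cohort")
        df = cohort.copy()
        df["model"] = label
        df["predicted_age"] = pred
        df["bag"] = compute_bag(df["age"].to_numpy(), pred)
        df["age_bin"] = assign_age_bin(df["age"].to_numpy())
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _complete_cases(bag_table: pd.DataFrame, covariates) -> tuple[pd.DataFrame, int]:
    cols = ["bag", "age", "group", "model", "participant", *covariates]
    keep = bag_table[[c for c in cols if c in bag_table.columns]].notna().all(axis=1)
    complete_ids = (
        bag_table.loc[keep, "participant"]
        .groupby(bag_table.loc[keep, "participant"]).size()
    )
    n_models = bag_table["model"].nunique()
    full = complete_ids[complete_ids == n_models].index
    out = bag_table[bag_table["participant"].isin(full) & keep]
    n_dropped = bag_table["participant"].nunique() - len(full)
    return out.copy(), n_dropped


def _between_formula(covariates, include_age: bool) -> str:
    terms = ["C(group, Sum)"]
    if include_age:
        terms += ["age", "C(group, Sum):age"]
    for cov in covariates:
        terms.append(f"C({cov}, Sum)" if cov in ("gender", "handedness") else cov)
    return "bag_mean ~ " + " + ".join(terms)


def rm_ancova(bag_table: pd.DataFrame, covariates=DEFAULT_COVARIATES,
              include_age: bool = True) -> dict:
    """Mixed-design RM-ANCOVA on BAG.

    Between-subject effects (Group, Age, Group x Age, covariates) are
    tested on subject-mean BAG with type-III sums of squares; the
    within-subject Model effect and Model x Group interaction are tested
    on the repeated measures with Greenhouse-Geisser correction when
    sphericity is violated. Rows with missing covariates are dropped
    listwise (count reported). Covariates enter as between-subject main
    effects only.
    """
    data, n_dropped = _complete_cases(bag_table, covariates)
    if data.empty or data["group"].nunique() < 2:
        raise ValueError("singular design: fewer than 2 groups after listwise deletion")
    counts = data.groupby("group")["participant"].nunique()
    if (counts == 0).any():
        raise ValueError(f"empty group cell(s): {counts[counts == 0].index.tolist()}")

    wide = data.pivot_table(index="participant", columns="model", values="bag")
    between = (
        data.drop_duplicates("participant")
        .set_index("participant")
        .loc[wide.index, ["age", "group", *covariates]]
    )
    between["bag_mean"] = wide.mean(axis=1)

    ols = smf.ols(_between_formula(covariates, include_age), data=between).fit()
    aov = sm.stats.anova_lm(ols, typ=3)
    ss_resid = float(aov.loc["Residual", "sum_sq"])
    df_resid = float(aov.loc["Residual", "df"])
    rename = {"C(group, Sum)": "Group", "age": "Age", "C(group, Sum):age": "Group x Age",
              "C(gender, Sum)": "gender", "C(handedness, Sum)": "handedness"}
    results: list[AncovaResult] = []
    for row in aov.index:
        if row in ("Intercept", "Residual"):
            continue
        ss = float(aov.loc[row, "sum_sq"])
        results.append(AncovaResult(
            effect=rename.get(row, row),
            F=float(aov.loc[row, "F"]),
            df1=float(aov.loc[row, "df"]), df2=df_resid,
            p=float(aov.loc[row, "PR(>F)"]),
            partial_eta_sq=ss / (ss + ss_resid),
        ))

    sphericity = None
    n_models = wide.shape[1]
    within_dev = wide.to_numpy() - wide.to_numpy().mean(axis=1, keepdims=True)
    if n_models < 2 or np.allclose(within_dev, 0.0, atol=1e-12):
        # no within-subject variance: Model effects are exactly null
        for eff in (["Model", "Model x Group"] if n_models >= 2 else []):
            df1 = float(n_models - 1) if eff == "Model" \
                else float((n_models - 1) * (between["group"].nunique() - 1))
            results.append(AncovaResult(eff, 0.0, df1,
                                        float((n_models - 1) * (len(wide) - between["group"].nunique())),
                                        1.0, 0.0, correction="degenerate"))
    else:
        from scipy import stats as sps

        long = data[["participant", "model", "bag", "group"]]
        mixed = pg.mixed_anova(data=long, dv="bag", within="model",
                               subject="participant", between="group",
                               correction=True)
        model_row = mixed[mixed["Source"] == "model"].iloc[0]
        eps = float(model_row["eps"]) if np.isfinite(model_row.get("eps", np.nan)) else 1.0
        if "W_spher" in mixed.columns and np.isfinite(model_row.get("W_spher", np.nan)):
            sphericity = {"W": float(model_row["W_spher"]),
                          "p": float(model_row["p_spher"]),
                          "spherical": bool(model_row["sphericity"])}
        # GG correction is applied to within-subject terms when sphericity is
        # violated (pingouin corrects the Model row; the interaction row's
        # corrected p is recomputed from the same epsilon)
        use_gg = sphericity is not None and not sphericity["spherical"]
        for src, label in (("model", "Model"), ("Interaction", "Model x Group")):
            row = mixed[mixed["Source"] == src].iloc[0]
            F = float(row["F"])
            df1, df2 = float(row["DF1"]), float(row["DF2"])
            if use_gg:
                p = float(sps.f.sf(F, eps * df1, eps * df2))
                df1, df2 = eps * df1, eps * df2
            else:
                p = float(row["p_unc"])
            results.append(AncovaResult(
                effect=label, F=F, df1=df1, df2=df2, p=p,
                partial_eta_sq=float(row["np2"]) if np.isfinite(row["np2"]) else 0.0,
                correction="greenhouse-geisser" if use_gg else "none",
            ))

    return {
        "effects": results,
        "n_subjects": len(wide),
        "n_dropped": n_dropped,
        "sphericity": sphericity,
        "bin_counts": data.drop_duplicates("participant")["age_bin"].value_counts().sort_index().to_dict()
        if "age_bin" in data.columns else None,
    }


def posthoc_pairwise(bag_table: pd.DataFrame, factor: str = "group",
                     dv: str = "bag", correction: str = "bonferroni",
                     paired: bool | None = None) -> pd.DataFrame:
    """All pairwise level comparisons with Bonferroni-scaled p-values.

    ``factor="model"`` comparisons are paired within participant;
    between-group comparisons use independent-sample tests. Cohen's d is
    the paired-difference d for paired tests, pooled-SD d otherwise.
    """
    from itertools import combinations
    from scipy import stats as sps

    if paired is None:
        paired = factor == "model"
    levels = list(pd.unique(bag_table[factor]))
    if len(levels) < 2:
        raise ValueError("factor needs at least 2 levels")
    pairs = list(combinations(levels, 2))
    rows = []
    for a, b in pairs:
        if paired:
            wide = bag_table.pivot_table(index="participant", columns=factor, values=dv)
            x, y = wide[a].dropna(), wide[b].dropna()
            common = x.index.intersection(y.index)
            x, y = x.loc[common].to_numpy(), y.loc[common].to_numpy()
            diff = x - y
            if np.all(diff == 0):
                t, p, d = 0.0, 1.0, 0.0
            else:
                t, p = sps.ttest_rel(x, y)
                d = diff.mean() / diff.std(ddof=1)
        else:
            x = bag_table.loc[bag_table[factor] == a, dv].dropna().to_numpy()
            y = bag_table.loc[bag_table[factor] == b, dv].dropna().to_numpy()
            t, p = sps.ttest_ind(x, y)
            pooled = np.sqrt(((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1))
                             / (len(x) + len(y) - 2))
            d = (x.mean() - y.mean()) / pooled if pooled > 0 else 0.0
        p_corr = min(1.0, float(p) * len(pairs)) if correction == "bonferroni" else float(p)
        rows.append({"level_a": a, "level_b": b,
                     "mean_diff": float(np.mean(x) - np.mean(y)),
                     "cohens_d": float(d), "p_uncorrected": float(p),
                     "p_corrected": p_corr})
    return pd.DataFrame(rows)


def _zscore(s: pd.Series) -> pd.Series:
    sd = s.std(ddof=0)
    return (s - s.mean()) / sd if sd > 0 else s * 0.0


def towre_regression(bag_table: pd.DataFrame, model_label: str,
                     covariates=DEFAULT_COVARIATES, alpha: float = 0.05,
                     bin_followup: bool = True) -> dict:
    """Continuous reading-skill regression: BAG ~ age + TOWRE + age x TOWRE + covariates.

    Continuous predictors and the interaction column are standardized
    (and so is BAG), so coefficients are standardized betas. When the
    age x TOWRE interaction is significant, simple-effects regressions of
    BAG on TOWRE are run within each age bin with within-bin
    standardization (controlling age and covariates).
    """
    sub = bag_table[bag_table["model"] == model_label].copy()
    cols = ["bag", "age", "towre_index", *covariates]
    sub = sub.dropna(subset=[c for c in cols if c in sub.columns])
    if sub.empty:
        raise ValueError("no complete cases")

    def design(frame: pd.DataFrame) -> pd.DataFrame:
        d = pd.DataFrame(index=frame.index)
        d["age"] = _zscore(frame["age"])
        d["towre"] = _zscore(frame["towre_index"])
        d["towre_x_age"] = _zscore(frame["age"] * frame["towre_index"])
        for cov in covariates:
            if cov not in frame.columns:
                continue
            if frame[cov].dtype == object:
                d[cov] = (frame[cov] == sorted(frame[cov].unique())[0]).astype(float)
            else:
                d[cov] = _zscore(frame[cov])
        return d

    X = sm.add_constant(design(sub))
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(_zscore(sub["bag"]), X).fit()
    coef = pd.DataFrame({
        "beta": fit.params, "t": fit.tvalues, "p": fit.pvalues,
    }).drop(index="const")

    per_bin = None
    if bin_followup and coef.loc["towre_x_age", "p"] < alpha:
        rows = []
        for b, frame in sub.groupby("age_bin"):
            if len(frame) < len(covariates) + 4:
                continue
            Xb = sm.add_constant(design(frame))
            Xb = Xb.loc[:, Xb.std() > 0]  # drop constant-within-bin columns
            fb = sm.OLS(_zscore(frame["bag"]), Xb).fit()
            if "towre" not in fb.params:
                continue
            rows.append({"age_bin": int(b), "n": len(frame),
                         "beta_towre": float(fb.params["towre"]),
                         "t": float(fb.tvalues["towre"]),
                         "p": float(fb.pvalues["towre"])})
        per_bin = pd.DataFrame(rows)

    return {"coefficients": coef, "per_bin": per_bin,
            "f_overall": float(fit.fvalue), "p_overall": float(fit.f_pvalue),
            "n": len(sub)}
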