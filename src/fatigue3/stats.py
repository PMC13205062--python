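"""Stage statistics: mixed-effects models, Holm contrasts, auxiliary tests.

Each feature is modeled separately and per paradigm as
``feature ~ stage + (1 | participant)`` (REML).  Estimated marginal means
are the model-implied stage means; the three pairwise stage contrasts use
a normal (Wald) approximation and Holm step-down adjustment within the
feature's three-contrast family.  Direction codes follow the convention
of significance tables: an arrow only when the adjusted p is below alpha.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

from .config import STAGES, StatsConfig

CONTRASTS = (("NonF", "ModF"), ("ModF", "SevF"), ("NonF", "SevF"))


@dataclass
class Contrast:
    pair: tuple[str, str]
    estimate: float
    p_raw: float
    p_holm: float = np.nan
    direction: str = "NS"


@dataclass
class LMMResult:
    feature: str
    paradigm: str
    emm: dict[str, float]
    emm_ci: dict[str, tuple[float, float]]
    contrasts: list[Contrast]
    var_subject: float
    var_residual: float
    singular: bool = False
    n_obs: int = 0


def holm_adjust(p_values: list[float] | np.ndarray) -> np.ndarray:
    """Step-down Holm adjustment with monotonicity enforcement, capped at 1."""
    p = np.asarray(p_values, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = min(1.0, (m - rank) * p[idx])
        running = max(running, val)
        adj[idx] = running
    return adj


def fit_lmm(
    values: np.ndarray,
    stages: np.ndarray,
    subjects: np.ndarray,
    feature: str = "feature",
    paradigm: str = "",
    cfg: StatsConfig | None = None,
) -> LMMResult:
    """REML fit of feature ~ stage with a participant random intercept.

    Missing observations are dropped.  On a singular random-effects fit
    the model falls back to ordinary least squares, flagged in the result.
    Contrasts are (later - earlier) stage differences on the model scale.
    """
    cfg = cfg or StatsConfig()
    df = pd.DataFrame(
        {"y": np.asarray(values, float), "stage": stages, "subject": subjects}
    ).dropna()
    present = [s for s in STAGES if s in set(df["stage"])]
    if len(present) < 2:
        raise ValueError("need at least two stages with data")
    if df["subject"].nunique() < 2:
        raise ValueError("need at least two subjects")
    df["stage"] = pd.Categorical(df["stage"], categories=present, ordered=True)

    singular = False
    var_subj = 0.0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm("y ~ C(stage)", df, groups=df["subject"])
            fit = model.fit(reml=True)  # BFGS; lbfgs can stall silently here
        params = fit.fe_params
        cov = fit.cov_params().iloc[: len(params), : len(params)]
        var_subj = float(fit.cov_re.iloc[0, 0])
        var_resid = float(fit.scale)
        if not np.isfinite(params).all() or not np.isfinite(cov.to_numpy()).all():
            raise ValueError("non-finite mixed-model fit")
    except Exception:
        singular = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.ols("y ~ C(stage)", df).fit()
        params = fit.params
        cov = fit.cov_params()
        var_resid = float(fit.mse_resid)

    # design rows mapping stages to fixed-effect coefficients
    design = {}
    for s in present:
        row = np.zeros(len(params))
        row[0] = 1.0
        for j, name in enumerate(params.index):
            if name == f"C(stage)[T.{s}]":
                row[j] = 1.0
        design[s] = row
    covm = cov.to_numpy()
    z = sps.norm.ppf(0.975)
    emm, emm_ci = {}, {}
    for s in present:
        r = design[s]
        mu = float(r @ params.to_numpy())
        se = float(np.sqrt(r @ covm @ r))
        emm[s] = mu
        emm_ci[s] = (mu - z * se, mu + z * se)

    contrasts: list[Contrast] = []
    for a, b in CONTRASTS:
        if a not in present or b not in present:
            contrasts.append(Contrast((a, b), np.nan, np.nan))
            continue
        L = design[b] - design[a]
        est = float(L @ params.to_numpy())
        se = float(np.sqrt(L @ covm @ L))
        if se == 0:
            p = 1.0
        else:
            p = float(2 * sps.norm.sf(abs(est) / se))
        contrasts.append(Contrast((a, b), est, p))

    avail = [c for c in contrasts if np.isfinite(c.p_raw)]
    if avail:
        adj = holm_adjust([c.p_raw for c in avail])
        for c, pa in zip(avail, adj):
            c.p_holm = float(pa)
            if pa < cfg.alpha and c.estimate > 0:
                c.direction = "up"
            elif pa < cfg.alpha and c.estimate < 0:
                c.direction = "down"
    return LMMResult(
        feature, paradigm, emm, emm_ci, contrasts, var_subj, var_resid,
        singular, len(df),
    )


def friedman_stage_test(block_values: np.ndarray) -> tuple[float, float]:
    """Friedman chi-square over a complete subjects x stages block design.

    ``block_values``: shape (n_subjects, k_stages); rows with missing cells
    are dropped with a warning.
    """
    x = np.asarray(block_values, float)
    keep = np.all(np.isfinite(x), axis=1)
    if keep.sum() < x.shape[0]:
        warnings.warn(f"{int((~keep).sum())} subjects dropped (incomplete blocks)")
    x = x[keep]
    if x.shape[0] < 2:
        raise ValueError("Friedman test needs at least two complete subjects")
    if np.allclose(x, x[:, [0]]):
        return 0.0, 1.0
    stat, p = sps.friedmanchisquare(*[x[:, j] for j in range(x.shape[1])])
    return float(stat), float(p)


@dataclass
class TransitionTimeReport:
    shapiro: dict[str, tuple[float, float]]
    anova: pd.DataFrame
    marginal_means: dict[str, tuple[float, float, float]]  # mean, lo, hi
    n_subjects: int


def transition_time_tests(times: pd.DataFrame) -> TransitionTimeReport:
    """Normality and two-way repeated-measures ANOVA on transition times.

    ``times`` columns: subject, paradigm (active/passive), transition
    (first/second), time_min.  Subjects missing any of the four cells are
    excluded.  Shapiro-Wilk runs per cell; the ANOVA has both factors
    within-subject.
    """
    import pingouin as pg

    df = times.dropna().copy()
    counts = df.groupby("subject").size()
    complete = counts[counts == 4].index
    dropped = set(df["subject"]) - set(complete)
    if dropped:
        warnings.warn(f"subjects excluded (incomplete design): {sorted(dropped)}")
    df = df[df["subject"].isin(complete)]
    if df["subject"].nunique() < 3:
        raise ValueError("too few complete subjects for the repeated-measures ANOVA")

    shapiro = {}
    for (par, tr), cell in df.groupby(["paradigm", "transition"]):
        vals = cell["time_min"].to_numpy()
        if np.ptp(vals) == 0:
            shapiro[f"{par}:{tr}"] = (np.nan, np.nan)
        else:
            w, p = sps.shapiro(vals)
            shapiro[f"{par}:{tr}"] = (float(w), float(p))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.rm_anova(
            data=df, dv="time_min", within=["paradigm", "transition"],
            subject="subject", detailed=True,
        )

    marg = {}
    t = sps.t.ppf(0.975, df["subject"].nunique() - 1)
    for factor in ("paradigm", "transition"):
        for level, cell in df.groupby(factor):
            per_subj = cell.groupby("subject")["time_min"].mean()
            m = float(per_subj.mean())
            se = float(per_subj.std(ddof=1) / np.sqrt(len(per_subj)))
            marg[f"{factor}:{level}"] = (m, m - t * se, m + t * se)
    return TransitionTimeReport(shapiro, aov, marg, df["subject"].nunique())


_ARROW = {"up": "↑", "down": "↓", "NS": "NS"}


def direction_table(results: list[LMMResult]) -> pd.DataFrame:
    """Long-format direction matrix: one row per feature x contrast with code."""
    rows = []
    for r in results:
        for c in r.contrasts:
            rows.append(
                {
                    "feature": r.feature,
                    "paradigm": r.paradigm,
                    "contrast": f"{c.pair[0]}→{c.pair[1]}",
                    "estimate": c.estimate,
                    "p_raw": c.p_raw,
                    "p_holm": c.p_holm,
                    "direction": _ARROW[c.direction],
                }
            )
    return pd.DataFrame(rows)


def results_to_json(results: list[LMMResult]) -> dict:
    out = {}
    for r in results:
        out[f"{r.paradigm}:{r.feature}"] = {
            "emm": r.emm,
            "emm_ci": {k: list(v) for k, v in r.emm_ci.items()},
            "contrasts": [
                {
                    "pair": list(c.pair),
                    "estimate": c.estimate,
                    "p_raw": c.p_raw,
                    "p_holm": c.p_holm,
                    "direction": c.direction,
                }
                for c in r.contrasts
            ],
            "var_subject": r.var_subject,
            "var_residual": r.var_residual,
            "singular_fallback_ols": r.singular,
            "n_obs": r.n_obs,
            "df_method": "normal (Wald/z) approximation",
        }
    return out


def make_report(
    results: list[LMMResult],
    out_dir: str | Path,
    extra_tests: dict | None = None,
) -> Path:
    """Write lmm_results.tsv, direction_table.tsv, results.json and report.md."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = direction_table(results)
    table.to_csv(out / "direction_table.tsv", sep="\t", index=False, na_rep="NA",
                 float_format="%.12g")

    emm_rows = []
    for r in results:
        for s, mu in r.emm.items():
            lo, hi = r.emm_ci[s]
            emm_rows.append(
                {
                    "feature": r.feature, "paradigm": r.paradigm, "stage": s,
                    "emm": mu, "ci_lo": lo, "ci_hi": hi,
                    "var_subject": r.var_subject, "var_residual": r.var_residual,
                }
            )
    pd.DataFrame(emm_rows).to_csv(
        out / "lmm_results.tsv", sep="\t", index=False, na_rep="NA",
        float_format="%.12g",
    )

    payload = {"lmm": results_to_json(results)}
    if extra_tests:
        payload.update(extra_tests)
    (out / "results.json").write_text(json.dumps(payload, indent=1, default=str))

    lines = ["# Stage statistics report", ""]
    lines.append("Direction codes: ↑/↓ significant (Holm-adjusted p < 0.05) "
                 "increase/decrease between stages, NS otherwise.")
    lines.append("")
    for paradigm in sorted({r.paradigm for r in results}):
        lines.append(f"## Paradigm: {paradigm}")
        lines.append("")
        lines.append("| feature | " + " | ".join(f"{a}→{b}" for a, b in CONTRASTS) + " |")
        lines.append("|---" * 4 + "|")
        for r in [r for r in results if r.paradigm == paradigm]:
            cells = " | ".join(_ARROW[c.direction] for c in r.contrasts)
            lines.append(f"| {r.feature} | {cells} |")
        lines.append("")
    path = out / "report.md"
    path.write_text("\n".join(lines))
    return path
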