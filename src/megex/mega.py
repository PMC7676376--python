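"""Per-gene multi-study mega-analysis of case/control expression.

The effect size is the log2 fold change (LFC): for each case sample the log2
ratio of its expression to the control-group mean, averaged over cases. Per
gene, the study-level LFCs are combined with an inverse-variance fixed-effect
model or a DerSimonian-Laird random-effects model; the model is chosen from
Cochran's Q: when the total dispersion Q is at most its degrees of freedom
(k - 1) the heterogeneity index I2 is clamped to zero and the fixed-effect
model is used, otherwise the random-effects model.  "Mega" (rather than
"meta") because the per-study effects are recomputed from the original
expression matrices, not taken from published summary statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientStudiesError, LfcUndefinedError
from .expression import StudyDataset

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)

__all__ = [
    "GeneEffect",
    "MetaResult",
    "gene_lfc",
    "study_gene_effects",
    "cochran_q",
    "i_squared",
    "combine_fixed",
    "combine_random",
    "meta_combine",
    "mega_analyze",
    "mega_analyze_collection",
    "select_significant",
    "results_frame",
]


@dataclass(frozen=True)
class GeneEffect:
    """One gene's effect size in one study."""

    study_id: str
    gene: str
    lfc: float  # log2 fold change, case vs control-group mean
    var: float  # within-study sampling variance of lfc
    n_case: int
    n_control: int


@dataclass
class MetaResult:
    """Combined multi-study result for one gene."""

    gene: str
    k: int  # number of contributing studies (#Study)
    effect: float  # combined LFC from the selected model
    se: float
    p: float  # two-sided Wald p of the combined effect
    q: float  # Cochran's Q
    df: int  # k - 1
    isq: float  # I2 heterogeneity percentage, clamped at 0
    q_p: float  # upper-tail chi-square probability of Q
    tau2: float  # DerSimonian-Laird between-study variance estimate
    model: str  # "fixed" or "random"
    # audit trail: both models are always computed and retained
    fixed: tuple[float, float, float] = field(default=(np.nan,) * 3)
    random: tuple[float, float, float] = field(default=(np.nan,) * 3)


def _lfc_and_var(
    case: np.ndarray, control: np.ndarray, control_mean: str
) -> tuple[float, float]:
    n_case = case.size
    n_ctrl = control.size
    log_case = np.log2(case)
    if control_mean == "geometric":
        # log-scale throughout: mean of case log2 minus mean of control log2
        log_ctrl = np.log2(control)
        lfc = float(np.mean(log_case) - np.mean(log_ctrl))
        var_case = float(np.var(log_case, ddof=1)) / n_case
        var_ctrl = float(np.var(log_ctrl, ddof=1)) / n_ctrl
    else:  # arithmetic control mean on the linear scale
        ctrl_mean = float(np.mean(control))
        lfc = float(np.mean(log_case)) - math.log2(ctrl_mean)
        var_case = float(np.var(log_case, ddof=1)) / n_case
        # delta-method term for the uncertainty of log2(control mean)
        var_ctrl = float(np.var(control, ddof=1)) / (
            n_ctrl * ctrl_mean**2 * LN2**2
        )
    return lfc, var_case + var_ctrl


def gene_lfc(
    study: StudyDataset, gene: str, control_mean: str = "geometric"
) -> GeneEffect | None:
    """Effect size of one gene in one study, or None when the gene is absent.

    The LFC is the mean over case samples of the log2 ratio of the case
    value to the control-group mean.  With control_mean="geometric" (the
    default) the control mean is taken on the log2 scale, so the estimator
    is the difference of group means of log2 expression — unbiased when
    log-scale noise is symmetric, and identical to the ratio form applied
    to log-stored matrices.  With "arithmetic" the control mean is the
    plain average of linear-scale values and the variance carries a
    delta-method term for its uncertainty; under skewed (e.g. log-normal)
    noise this variant is shifted by about -sigma2*ln2/2.

    The variance sums both groups' sampling noise: the case-sample variance
    of the per-case log2 ratios over n_case plus the control-mean term.

    Raises
    ------
    LfcUndefinedError
        If the control-group mean is not strictly positive.
    """
    if control_mean not in ("geometric", "arithmetic"):
        raise ValueError(f"unknown control_mean {control_mean!r}")
    if gene not in study.matrix.index:
        return None
    row = study.matrix.loc[gene].to_numpy(dtype=float)
    groups = np.asarray(study.groups)
    case = row[groups == "case"]
    control = row[groups == "control"]
    if float(np.mean(control)) <= 0:
        raise LfcUndefinedError(
            f"non-positive control mean for gene {gene!r} in study "
            f"{study.study_id!r}"
        )
    case = case[case > 0]
    if control_mean == "geometric":
        control = control[control > 0]
    if case.size < 2 or control.size < 2:
        return None
    lfc, var = _lfc_and_var(case, control, control_mean)
    return GeneEffect(
        study_id=study.study_id,
        gene=gene,
        lfc=lfc,
        var=var,
        n_case=int(case.size),
        n_control=int(control.size),
    )


def study_gene_effects(
    study: StudyDataset, control_mean: str = "geometric"
) -> pd.DataFrame:
    """Vectorized `gene_lfc` over every gene of a study.

    Returns a frame indexed by gene with columns lfc, var, n_case, n_control.
    Genes with a non-positive control mean or with fewer than two positive
    case (or, for the geometric mean, control) values are dropped with a
    warning, mirroring the scalar contract where they raise or return the
    absent marker.
    """
    if control_mean not in ("geometric", "arithmetic"):
        raise ValueError(f"unknown control_mean {control_mean!r}")
    groups = np.asarray(study.groups)
    mat = study.matrix.to_numpy(dtype=float)
    case = mat[:, groups == "case"]
    control = mat[:, groups == "control"]
    ctrl_lin_mean = control.mean(axis=1)
    ok = ctrl_lin_mean > 0
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning(
            "study %s: %d gene(s) dropped (non-positive control mean)",
            study.study_id,
            n_bad,
        )
    pos_case = case > 0
    n_case = pos_case.sum(axis=1)
    ok &= n_case >= 2
    ok &= control.shape[1] >= 2
    with np.errstate(divide="ignore", invalid="ignore"):
        log_case = np.where(pos_case, np.log2(np.where(pos_case, case, 1.0)), np.nan)
        mean_case = np.nanmean(log_case, axis=1)
        var_case = np.nanvar(log_case, axis=1, ddof=1) / n_case
    n_ctrl = control.shape[1]
    if control_mean == "geometric":
        pos_ctrl = control > 0
        n_ctrl_pos = pos_ctrl.sum(axis=1)
        ok &= n_ctrl_pos >= 2
        with np.errstate(divide="ignore", invalid="ignore"):
            log_ctrl = np.where(
                pos_ctrl, np.log2(np.where(pos_ctrl, control, 1.0)), np.nan
            )
            lfc = mean_case - np.nanmean(log_ctrl, axis=1)
            var_ctrl = np.nanvar(log_ctrl, axis=1, ddof=1) / n_ctrl_pos
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            lfc = mean_case - np.log2(np.where(ok, ctrl_lin_mean, 1.0))
            var_ctrl = control.var(axis=1, ddof=1) / (
                n_ctrl * ctrl_lin_mean**2 * LN2**2
            )
    out = pd.DataFrame(
        {
            "lfc": lfc,
            "var": var_case + var_ctrl,
            "n_case": n_case,
            "n_control": n_ctrl,
        },
        index=study.matrix.index,
    )
    return out.loc[ok]


def cochran_q(
    effects: Sequence[float], variances: Sequence[float]
) -> tuple[float, int, float]:
    """Cochran's Q with its degrees of freedom and upper-tail chi-square p.

    Q = sum_i w_i (y_i - ybar_w)^2 with w_i = 1/var_i and ybar_w the
    fixed-effect mean; df = k - 1.  q_p is the probability that a dispersion
    at least this large arises from within-study variance alone.
    """
    y = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    if y.size < 2:
        raise InsufficientStudiesError("cochran_q needs at least 2 studies")
    if np.any(v <= 0):
        raise ValueError("all variances must be positive")
    w = 1.0 / v
    ybar = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - ybar) ** 2))
    df = y.size - 1
    return q, df, float(stats.chi2.sf(q, df))


def i_squared(q: float, df: int) -> float:
    """I2 heterogeneity percentage: 100 (Q - df) / Q, clamped to 0 for Q <= df."""
    if q <= df:
        return 0.0
    return 100.0 * (q - df) / q


def combine_fixed(
    effects: Sequence[float], variances: Sequence[float]
) -> tuple[float, float, float]:
    """Inverse-variance fixed-effect combination: (effect, se, two-sided p)."""
    y = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    if y.size == 0:
        raise InsufficientStudiesError("combine_fixed needs at least 1 study")
    w = 1.0 / v
    effect = float(np.sum(w * y) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    p = float(2.0 * stats.norm.sf(abs(effect) / se))
    return effect, se, p


def combine_random(
    effects: Sequence[float], variances: Sequence[float]
) -> tuple[float, float, float, float]:
    """DerSimonian-Laird random-effects combination.

    tau2 = max(0, (Q - df) / C) with C = sum w_i - sum w_i^2 / sum w_i, then
    an inverse-variance combination with weights 1/(var_i + tau2).  Returns
    (effect, se, two-sided p, tau2).
    """
    y = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    if y.size < 2:
        raise InsufficientStudiesError("combine_random needs at least 2 studies")
    w = 1.0 / v
    q, df, _ = cochran_q(y, v)
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    w_star = 1.0 / (v + tau2)
    effect = float(np.sum(w_star * y) / np.sum(w_star))
    se = float(1.0 / math.sqrt(np.sum(w_star)))
    p = float(2.0 * stats.norm.sf(abs(effect) / se))
    return effect, se, p, tau2


def meta_combine(
    gene: str, effects: Sequence[GeneEffect]
) -> MetaResult:
    """Combine per-study effects for one gene under the Q-based model rule."""
    y = [e.lfc for e in effects]
    v = [e.var for e in effects]
    k = len(effects)
    if k < 2:
        raise InsufficientStudiesError(f"gene {gene!r}: k={k} < 2")
    q, df, q_p = cochran_q(y, v)
    isq = i_squared(q, df)
    fixed = combine_fixed(y, v)
    r_effect, r_se, r_p, tau2 = combine_random(y, v)
    model = "fixed" if q <= df else "random"
    effect, se, p = fixed if model == "fixed" else (r_effect, r_se, r_p)
    return MetaResult(
        gene=gene,
        k=k,
        effect=effect,
        se=se,
        p=p,
        q=q,
        df=df,
        isq=isq,
        q_p=q_p,
        tau2=tau2,
        model=model,
        fixed=fixed,
        random=(r_effect, r_se, r_p),
    )


def mega_analyze(
    gene: str,
    studies: Iterable[StudyDataset],
    min_studies: int = 2,
    control_mean: str = "geometric",
) -> MetaResult | None:
    """Mega-analyze one gene over a study collection.

    Gathers the gene's effect from every study that measured it (k = #Study),
    then combines under the heterogeneity-driven model selection.  Studies
    where the LFC is undefined (non-positive control mean) are excluded with
    a warning rather than aborting the gene.  Returns None (skipped marker)
    when fewer than `min_studies` studies contribute.
    """
    if min_studies < 2:
        raise ValueError("min_studies must be >= 2")
    effects: list[GeneEffect] = []
    for study in studies:
        try:
            eff = gene_lfc(study, gene, control_mean=control_mean)
        except LfcUndefinedError as exc:
            logger.warning("excluding %s from %s: %s", gene, study.study_id, exc)
            continue
        if eff is not None:
            effects.append(eff)
    if len(effects) < min_studies:
        return None
    return meta_combine(gene, effects)


def mega_analyze_collection(
    studies: Sequence[StudyDataset],
    genes: Sequence[str] | None = None,
    min_studies: int = 2,
    control_mean: str = "geometric",
) -> list[MetaResult]:
    """Mega-analyze every gene (or a given subset) across a study collection.

    Per-study effect tables are computed once, vectorized, so collections of
    thousands of genes are handled in seconds.
    """
    if min_studies < 2:
        raise ValueError("min_studies must be >= 2")
    tables = [study_gene_effects(s, control_mean=control_mean) for s in studies]
    ids = [s.study_id for s in studies]
    if genes is None:
        seen: dict[str, None] = {}
        for t in tables:
            for g in t.index:
                seen.setdefault(g, None)
        genes = list(seen)
    results = []
    for gene in genes:
        effects = [
            GeneEffect(
                study_id=sid,
                gene=gene,
                lfc=float(t.at[gene, "lfc"]),
                var=float(t.at[gene, "var"]),
                n_case=int(t.at[gene, "n_case"]),
                n_control=int(t.at[gene, "n_control"]),
            )
            for sid, t in zip(ids, tables)
            if gene in t.index
        ]
        if len(effects) < min_studies:
            continue
        results.append(meta_combine(gene, effects))
    return results


def select_significant(
    results: Iterable[MetaResult],
    p_max: float = 1e-7,
    lfc_min_abs: float = 1.0,
) -> list[MetaResult]:
    """Significance filter: strict p < p_max AND strict |effect| > lfc_min_abs.

    Returns the surviving results sorted by |effect| descending.
    """
    kept = [r for r in results if r.p < p_max and abs(r.effect) > lfc_min_abs]
    return sorted(kept, key=lambda r: -abs(r.effect))


def results_frame(results: Iterable[MetaResult]) -> pd.DataFrame:
    """Tabulate MetaResults (one row per gene, columns mirroring the report)."""
    rows = [
        {
            "gene": r.gene,
            "model_used": r.model,
            "k": r.k,
            "effect": r.effect,
            "se": r.se,
            "p": r.p,
            "Q": r.q,
            "df": r.df,
            "isq": r.isq,
            "q_p": r.q_p,
            "tau2": r.tau2,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "model_used", "k", "effect", "se", "p",
            "Q", "df", "isq", "q_p", "tau2",
        ],
    )
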