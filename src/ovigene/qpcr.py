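"""Relative tissue expression by the Livak 2^-ddCt method.

Quantification cycles (Ct) for a target gene and a reference gene (GAPDH)
are measured in technical triplicate for a small number of biological
replicates (animals) across a tissue panel.  The pipeline is:

1. average technical replicates within animal x tissue x gene;
2. dCt   = Ct(target) - Ct(reference), per animal and tissue;
3. ddCt  = dCt - mean dCt of the calibrator tissue;
4. fold change = 2 ** -ddCt.

The per-tissue fold change reported is ``2 ** -mean(ddCt)`` (so the
calibrator is exactly 1), with the SD of the per-animal fold changes as the
dispersion.  Differences among tissues are assessed with a one-way ANOVA on
per-animal fold changes, followed — only when the omnibus F is significant
(Fisher's protected LSD; Tukey HSD available) — by pairwise comparisons that
feed a compact letter display: tissues sharing no letter differ at the
chosen alpha.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TISSUES",
    "RelativeExpression",
    "AnovaResult",
    "relative_expression",
    "one_way_anova",
    "pairwise_lsd",
    "pairwise_tukey",
    "letter_display",
    "expression_report",
    "plot_expression",
]

#: the 13-tissue panel of the study design
TISSUES = (
    "hypothalamus", "hypophysis", "heart", "liver", "spleen", "lung",
    "kidney", "ovary", "oviduct", "uterus", "rumen", "duodenum",
    "longissimus dorsi",
)

CT_COLUMNS = ("animal", "tissue", "gene", "replicate", "ct")


@dataclass(frozen=True)
class RelativeExpression:
    target: str
    reference: str
    calibrator: str
    #: per-tissue summary: tissue, delta_ct, delta_delta_ct, fold_change, sd_fold
    summary: pd.DataFrame
    #: per-animal fold changes: tissue, animal, delta_ct, fold
    per_animal: pd.DataFrame

    def folds_by_tissue(self) -> dict[str, np.ndarray]:
        """Per-animal fold changes grouped by tissue (ANOVA input)."""
        return {t: g["fold"].to_numpy(dtype=float)
                for t, g in self.per_animal.groupby("tissue", sort=False)}


@dataclass(frozen=True)
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float
    ss_between: float
    ss_within: float

    @property
    def ms_within(self) -> float:
        return self.ss_within / self.df_within if self.df_within else float("nan")


def _validate_ct(ct: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table lacks columns {missing}")
    values = pd.to_numeric(ct["ct"])
    if not np.isfinite(values).all() or (values <= 0).any():
        raise ValueError("Ct values must be positive and finite")
    return ct


def relative_expression(
    ct: pd.DataFrame,
    target: str,
    reference: str,
    calibrator: str | None = None,
) -> RelativeExpression:
    """Livak relative quantification of ``target`` against ``reference``.

    ``calibrator`` names the tissue whose mean dCt defines ddCt = 0; when
    omitted, the least-expressed tissue (largest mean dCt, hence smallest
    fold change) is used, so the panel minimum sits at 1.
    """
    ct = _validate_ct(ct)
    present = set(ct["gene"])
    for gene in (target, reference):
        if gene not in present:
            raise ValueError(f"gene {gene!r} absent from the Ct table")

    # technical replicates -> one Ct per animal x tissue x gene
    mean_ct = (ct.groupby(["tissue", "animal", "gene"], sort=False)["ct"]
                 .mean().unstack("gene"))
    if mean_ct[reference].isna().any() or mean_ct[target].isna().any():
        bad = mean_ct.index[mean_ct[[target, reference]].isna().any(axis=1)]
        raise ValueError(f"missing target/reference Ct for {list(bad)[:3]}")

    per_animal = mean_ct.reset_index()
    per_animal["delta_ct"] = per_animal[target] - per_animal[reference]

    tissue_dct = per_animal.groupby("tissue", sort=False)["delta_ct"].mean()
    if calibrator is None:
        calibrator = str(tissue_dct.idxmax())
    elif calibrator not in tissue_dct.index:
        raise ValueError(f"calibrator tissue {calibrator!r} absent")
    base = float(tissue_dct.loc[calibrator])

    per_animal["delta_delta_ct"] = per_animal["delta_ct"] - base
    per_animal["fold"] = 2.0 ** (-per_animal["delta_delta_ct"])

    summary = (per_animal.groupby("tissue", sort=False)
               .agg(delta_ct=("delta_ct", "mean"),
                    delta_delta_ct=("delta_delta_ct", "mean"),
                    sd_fold=("fold", lambda v: float(np.std(v, ddof=1))
                             if len(v) > 1 else 0.0))
               .reset_index())
    summary["fold_change"] = 2.0 ** (-summary["delta_delta_ct"])
    summary = summary[["tissue", "delta_ct", "delta_delta_ct",
                       "fold_change", "sd_fold"]]

    return RelativeExpression(
        target=target, reference=reference, calibrator=calibrator,
        summary=summary,
        per_animal=per_animal[["tissue", "animal", "delta_ct",
                               "delta_delta_ct", "fold"]],
    )


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA decomposition.

    With zero within-group variance the F statistic is reported as ``inf``
    (p = 0) when group means differ and 0 (p = 1) when they do not.
    """
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least two groups")
    all_values = np.concatenate(list(arrays.values()))
    n_total = all_values.size
    k = len(arrays)
    df_between, df_within = k - 1, n_total - k
    if df_within < 1:
        raise ValueError("ANOVA needs at least one residual degree of freedom")

    grand = all_values.mean()
    ss_between = float(sum(a.size * (a.mean() - grand) ** 2
                           for a in arrays.values()))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrays.values()))

    if ss_within <= 1e-14 * max(1.0, float(all_values @ all_values)):
        if ss_between <= 1e-14 * max(1.0, float(all_values @ all_values)):
            f, p = 0.0, 1.0
        else:
            f, p = float("inf"), 0.0
    else:
        f = (ss_between / df_between) / (ss_within / df_within)
        p = float(stats.f.sf(f, df_between, df_within))
    return AnovaResult(f=f, df_between=df_between, df_within=df_within,
                       p=p, ss_between=ss_between, ss_within=ss_within)


def _pairwise_frame(names: Sequence[str], pmat: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(pmat, index=list(names), columns=list(names))


def pairwise_lsd(groups: Mapping[str, Sequence[float]],
                 anova: AnovaResult | None = None) -> pd.DataFrame:
    """Fisher LSD pairwise p-values using the pooled within-group MS."""
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    anova = anova or one_way_anova(arrays)
    names = list(arrays)
    n = len(names)
    pmat = np.ones((n, n))
    msw, dfw = anova.ms_within, anova.df_within
    for i, j in itertools.combinations(range(n), 2):
        a, b = arrays[names[i]], arrays[names[j]]
        diff = a.mean() - b.mean()
        if msw <= 0.0:
            p = 1.0 if diff == 0.0 else 0.0
        else:
            se = np.sqrt(msw * (1.0 / a.size + 1.0 / b.size))
            t = diff / se
            p = float(2.0 * stats.t.sf(abs(t), dfw))
        pmat[i, j] = pmat[j, i] = p
    return _pairwise_frame(names, pmat)


def pairwise_tukey(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Tukey HSD pairwise p-values (studentized-range test)."""
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    res = stats.tukey_hsd(*arrays)
    return _pairwise_frame(list(groups), np.asarray(res.pvalue))


def letter_display(pmat: pd.DataFrame | np.ndarray,
                   names: Sequence[str] | None = None,
                   alpha: float = 0.05) -> dict[str, str]:
    """Compact letter display by the insert-and-absorb algorithm.

    ``pmat`` is a symmetric pairwise p-value matrix with unit diagonal;
    ``names`` should already be in presentation order (means descending).
    Two groups share a letter exactly when their pairwise p >= alpha.
    """
    if isinstance(pmat, pd.DataFrame):
        names = list(pmat.columns) if names is None else list(names)
        matrix = pmat.to_numpy(dtype=float)
    else:
        matrix = np.asarray(pmat, dtype=float)
        names = [str(i) for i in range(matrix.shape[0])] if names is None else list(names)
    n = matrix.shape[0]
    if matrix.shape != (n, n) or not np.allclose(matrix, matrix.T, atol=1e-12):
        raise ValueError("pairwise p matrix must be square and symmetric")

    columns: list[set[int]] = [set(range(n))]
    for i, j in itertools.combinations(range(n), 2):
        if matrix[i, j] >= alpha:
            continue
        updated: list[set[int]] = []
        for col in columns:
            if i in col and j in col:
                updated.extend([col - {i}, col - {j}])
            else:
                updated.append(col)
        # absorb: drop empties, strict subsets of another column, duplicates
        columns = []
        for col in updated:
            if not col or any(col < other for other in updated):
                continue
            if col not in columns:
                columns.append(col)

    columns.sort(key=lambda c: (min(c), sorted(c)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {idx: "" for idx in range(n)}
    for pos, col in enumerate(columns):
        symbol = alphabet[pos] if pos < 26 else f"({pos})"
        for idx in sorted(col):
            letters[idx] += symbol
    return {names[idx]: letters[idx] for idx in range(n)}


def expression_report(
    ct: pd.DataFrame,
    target: str,
    reference: str,
    calibrator: str | None = None,
    alpha: float = 0.05,
    method: str = "lsd",
) -> pd.DataFrame:
    """Full tissue-expression table: mean fold, SD and significance letters.

    Letters come from a compact letter display over the pairwise test chosen
    by ``method`` ("lsd" = Fisher's protected LSD, "tukey" = Tukey HSD);
    with a non-significant omnibus ANOVA all tissues share the letter "a".
    Rows are ordered by mean fold change, descending.
    """
    rel = relative_expression(ct, target, reference, calibrator)
    groups = rel.folds_by_tissue()
    anova = one_way_anova(groups)

    order = (rel.summary.sort_values("fold_change", ascending=False)
             ["tissue"].tolist())
    if anova.p < alpha:
        if method == "lsd":
            pmat = pairwise_lsd(groups, anova)
        elif method == "tukey":
            pmat = pairwise_tukey(groups)
        else:
            raise ValueError(f"unknown post-hoc method {method!r}")
        pmat = pmat.loc[order, order]
        letters = letter_display(pmat, order, alpha=alpha)
    else:
        letters = {t: "a" for t in order}

    report = rel.summary.set_index("tissue").loc[order].reset_index()
    report["letters"] = [letters[t] for t in report["tissue"]]
    report = report.rename(columns={"fold_change": "mean_fold",
                                    "sd_fold": "sd"})
    report.attrs["anova"] = anova
    report.attrs["calibrator"] = rel.calibrator
    return report[["tissue", "mean_fold", "sd", "letters"]]


def plot_expression(report: pd.DataFrame, path: str, title: str = "") -> None:
    """Bar chart of mean fold changes with SD whiskers and letter labels."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    x = np.arange(len(report))
    ax.bar(x, report["mean_fold"], yerr=report["sd"], capsize=3,
           color="#888fc4", edgecolor="black")
    for xi, (fold, sd, letters) in enumerate(
            zip(report["mean_fold"], report["sd"], report["letters"])):
        ax.text(xi, fold + sd + 0.05 * report["mean_fold"].max(),
                letters, ha="center", fontsize=8)
    ax.set_xticks(x, report["tissue"], rotation=60, ha="right", fontsize=8)
    ax.set_ylabel("relative expression (2$^{-\\Delta\\Delta Ct}$)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
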