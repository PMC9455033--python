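"""Fixed-effects association model for litter size.

The model is the two-factor linear model

    Y_ijn = mu + P_i + G_j + (PG)_ij + e_ijn

with parity (1-3) and SNP genotype as fixed factors and their interaction.
Each ewe contributes one record per parity; litter size is the lamb count of
that lambing (in practice 1 or 2 for this breed).  The design is unbalanced
(genotype classes have very different sizes), so effects are coded
sum-to-zero and each term is tested with a partial (Type III) F-test:
the term's sum of squares is the increase in residual SS when its columns
are deleted from the otherwise full design.

Degenerate designs are handled explicitly: an empty parity-by-genotype cell
drops the interaction term (with a warning) rather than producing a rank-
deficient fit, and a zero-variance response reports non-computable F
statistics instead of dividing by zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssociationResult",
    "fit_association",
    "genotype_summary",
    "validate_phenotypes",
]

REQUIRED_COLUMNS = ("parity", "genotype", "litter_size")
VALID_PARITIES = (1, 2, 3)


@dataclass(frozen=True)
class AssociationResult:
    """ANOVA table, genotype summaries and the significance decision."""

    locus_id: str
    anova: pd.DataFrame  # term, sum_sq, df, F, p
    genotype_summaries: pd.DataFrame  # genotype, n, mean, sd
    overall_mean: float
    alpha: float
    significant: bool
    interaction_dropped: bool
    zero_variance: bool

    @property
    def genotype_p(self) -> float:
        return float(self.anova.loc[self.anova["term"] == "genotype", "p"].iloc[0])


def validate_phenotypes(pt: pd.DataFrame) -> pd.DataFrame:
    """Check the phenotype table invariants; returns the validated frame."""
    missing = [c for c in REQUIRED_COLUMNS if c not in pt.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns {missing}")
    parities = pd.to_numeric(pt["parity"])
    if not parities.isin(VALID_PARITIES).all():
        bad = sorted(set(parities) - set(VALID_PARITIES))
        raise ValueError(f"parity values outside {VALID_PARITIES}: {bad}")
    sizes = pd.to_numeric(pt["litter_size"])
    if (sizes < 1).any():
        raise ValueError("litter_size must be >= 1")
    if "animal_id" in pt.columns:
        dup = pt.duplicated(subset=["animal_id", "parity"])
        if dup.any():
            raise ValueError(
                f"animal contributes more than one record per parity "
                f"(first duplicate row {int(np.flatnonzero(dup)[0])})"
            )
    return pt


def _effect_code(values: pd.Series, levels: Sequence) -> np.ndarray:
    """Sum-to-zero (deviation) coding: k-1 columns, last level coded -1."""
    k = len(levels)
    index = {lvl: i for i, lvl in enumerate(levels)}
    x = np.zeros((len(values), k - 1))
    for row, v in enumerate(values):
        i = index[v]
        if i == k - 1:
            x[row, :] = -1.0
        else:
            x[row, i] = 1.0
    return x


def _sse(x: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid)


def fit_association(
    pt: pd.DataFrame,
    locus_id: str = "locus",
    alpha: float = 0.05,
) -> AssociationResult:
    """Fit the parity + genotype + interaction model and test each term.

    ``pt`` needs columns ``parity``, ``genotype``, ``litter_size`` (and
    optionally ``animal_id``, used only for the per-animal genotype summary
    and the one-record-per-parity check).
    """
    pt = validate_phenotypes(pt)
    y = pd.to_numeric(pt["litter_size"]).to_numpy(dtype=float)
    n = len(y)

    parity_levels = sorted(pd.to_numeric(pt["parity"]).unique())
    genotype_levels = sorted(pt["genotype"].unique())
    if len(genotype_levels) < 2:
        raise ValueError(f"{locus_id}: a single genotype class cannot be tested")

    xp = _effect_code(pd.to_numeric(pt["parity"]), parity_levels)
    xg = _effect_code(pt["genotype"], genotype_levels)

    cells = pd.crosstab(pt["parity"], pt["genotype"])
    full_grid = (cells.shape == (len(parity_levels), len(genotype_levels))
                 and (cells.to_numpy() > 0).all())
    interaction_dropped = not full_grid
    if interaction_dropped:
        warnings.warn(
            f"{locus_id}: empty parity x genotype cell(s); "
            "interaction term dropped from the model",
            UserWarning,
            stacklevel=2,
        )
        xi = np.empty((n, 0))
    else:
        xi = np.einsum("ni,nj->nij", xp, xg).reshape(n, -1)

    intercept = np.ones((n, 1))
    blocks = {"parity": xp, "genotype": xg}
    if xi.shape[1]:
        blocks["parity:genotype"] = xi
    x_full = np.hstack([intercept, *blocks.values()])

    rank = np.linalg.matrix_rank(x_full)
    df_resid = n - rank
    if df_resid <= 0:
        raise ValueError(
            f"{locus_id}: saturated design ({n} records, rank {rank}); "
            "no residual degrees of freedom"
        )
    sse_full = _sse(x_full, y)
    zero_variance = sse_full < 1e-10 * max(1.0, float(y @ y))
    ms_resid = sse_full / df_resid

    rows = []
    names = list(blocks)
    for name in names:
        reduced = np.hstack([intercept] +
                            [b for key, b in blocks.items() if key != name])
        ss = max(_sse(reduced, y) - sse_full, 0.0)
        df_term = blocks[name].shape[1]
        if zero_variance:
            f_stat, p = float("nan"), float("nan")
        else:
            f_stat = (ss / df_term) / ms_resid
            p = float(stats.f.sf(f_stat, df_term, df_resid))
        rows.append({"term": name, "sum_sq": ss, "df": df_term,
                     "F": f_stat, "p": p})
    if interaction_dropped:
        rows.append({"term": "parity:genotype", "sum_sq": float("nan"),
                     "df": 0, "F": float("nan"), "p": float("nan")})
    rows.append({"term": "residual", "sum_sq": sse_full, "df": df_resid,
                 "F": float("nan"), "p": float("nan")})
    anova = pd.DataFrame(rows)

    if zero_variance:
        warnings.warn(
            f"{locus_id}: zero-variance response; F statistics not computable",
            UserWarning,
            stacklevel=2,
        )

    beta, _, _, _ = np.linalg.lstsq(x_full, y, rcond=None)
    genotype_row = anova.loc[anova["term"] == "genotype"].iloc[0]
    significant = bool(np.isfinite(genotype_row["p"]) and genotype_row["p"] < alpha)

    return AssociationResult(
        locus_id=locus_id,
        anova=anova,
        genotype_summaries=genotype_summary(pt),
        overall_mean=float(beta[0]),
        alpha=alpha,
        significant=significant,
        interaction_dropped=interaction_dropped,
        zero_variance=zero_variance,
    )


def genotype_summary(pt: pd.DataFrame) -> pd.DataFrame:
    """Per-genotype n, mean and sample SD of per-animal mean litter size.

    Records are first averaged within animal (mean litter size over the
    recorded parities), then summarized per genotype class with the n-1
    denominator SD.  A single-animal class reports SD 0.0 and is flagged in
    the ``sd_flag`` column; a class whose animals all share one value
    likewise reports 0.0 without a flag.
    """
    pt = validate_phenotypes(pt)
    if "animal_id" in pt.columns:
        per_animal = (pt.groupby(["animal_id", "genotype"], sort=False)
                        ["litter_size"].mean().reset_index())
    else:
        per_animal = pt[["genotype", "litter_size"]].copy()
    rows = []
    for genotype, group in per_animal.groupby("genotype", sort=True):
        values = group["litter_size"].to_numpy(dtype=float)
        sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
        rows.append({
            "genotype": genotype,
            "n": len(values),
            "mean": float(np.mean(values)),
            "sd": sd,
            "sd_flag": "n=1" if len(values) == 1 else "",
        })
    return pd.DataFrame(rows)
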