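"""Per-locus population-genetic summaries for SNP genotyping data.

Given per-animal genotype calls (or a pre-tallied genotype table) at a single
locus, this module computes genotype and allele frequencies, gene-diversity
indices and the Hardy-Weinberg chi-square goodness-of-fit test — the standard
descriptive battery of a candidate-gene study.

A note on ``Ho`` (homozygosity): throughout this package homozygosity is the
*expected* homozygosity (gene identity) ``sum(p_i^2)`` computed from allele
frequencies — the complement of Nei's gene diversity ``He = 1 - sum(p_i^2)``
— not the observed fraction of homozygous animals.  The two coincide only
under Hardy-Weinberg proportions, and the expected form is what population
summaries of this kind conventionally tabulate alongside ``He``, ``Ne`` and
``PIC``.

PIC is Botstein's polymorphism information content::

    PIC = 1 - sum_i p_i^2 - sum_{i<j} 2 p_i^2 p_j^2

classified as low (< 0.25), moderate (0.25–0.5) or high (> 0.5); the interval
boundaries are included in the moderate class.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeCounts",
    "AlleleFrequencies",
    "DiversityIndices",
    "HWETestResult",
    "tabulate_genotypes",
    "counts_from_mapping",
    "genotype_frequencies",
    "allele_frequencies",
    "diversity_indices",
    "hwe_chi_square",
    "locus_summary",
    "read_genotype_csv",
    "read_counts_csv",
]

#: genotype codes treated as missing and excluded from N
MISSING_CODES = {"", ".", "./.", "NA", "N/A", "--", "NN"}

#: minimum expected genotype count before the classical chi-square
#: approximation is flagged as questionable
MIN_EXPECTED = 5.0


def _parse_genotype(raw: object) -> tuple[str, str] | None:
    """Parse one genotype call into an unordered allele pair.

    Accepts two-character strings ("AG"), slash-separated calls ("A/G") and
    returns ``None`` for missing codes.  Heterozygote order is irrelevant:
    "AG" and "GA" map to the same pair.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    text = str(raw).strip().upper()
    if text in MISSING_CODES:
        return None
    alleles = text.split("/") if "/" in text else list(text)
    if len(alleles) != 2 or not all(a.isalnum() and a for a in alleles):
        raise ValueError(f"unparseable genotype {raw!r}")
    a, b = sorted(alleles)
    return a, b


def _pair_label(pair: tuple[str, str]) -> str:
    return "".join(pair)


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype tally for one locus.

    ``counts`` maps the unordered allele pair (as a sorted tuple) to the
    number of animals carrying it.  ``n_missing`` records how many input rows
    were excluded as missing.
    """

    locus_id: str
    alleles: tuple[str, ...]
    counts: Mapping[tuple[str, str], int]
    n_missing: int = 0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"{self.locus_id}: no genotyped animals")
        for pair, count in self.counts.items():
            if count < 0 or int(count) != count:
                raise ValueError(f"{self.locus_id}: bad count {count} for {pair}")
            for a in pair:
                if a not in self.alleles:
                    raise ValueError(
                        f"{self.locus_id}: allele {a!r} of genotype {pair} "
                        f"not in allele set {self.alleles}"
                    )

    @property
    def n(self) -> int:
        """Number of successfully genotyped animals."""
        return int(sum(self.counts.values()))

    def count(self, genotype: str) -> int:
        pair = tuple(sorted(genotype))
        return int(self.counts.get(pair, 0))  # type: ignore[call-overload]


@dataclass(frozen=True)
class AlleleFrequencies:
    locus_id: str
    freqs: Mapping[str, float]

    def __post_init__(self) -> None:
        total = float(sum(self.freqs.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.locus_id}: allele frequencies sum to {total}")
        if any(f < 0 or f > 1 for f in self.freqs.values()):
            raise ValueError(f"{self.locus_id}: frequency outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.asarray(list(self.freqs.values()), dtype=float)


@dataclass(frozen=True)
class DiversityIndices:
    """Ho / He / Ne / PIC bundle for one locus."""

    locus_id: str
    ho: float
    he: float
    ne: float
    pic: float
    pic_class: str


@dataclass(frozen=True)
class HWETestResult:
    locus_id: str
    expected_counts: Mapping[str, float]
    chi2: float
    df: int
    p_value: float
    #: genotype classes whose expected count falls below MIN_EXPECTED
    low_expected: tuple[str, ...] = ()


def tabulate_genotypes(
    records: pd.DataFrame | Iterable[object],
    locus: str | None = None,
    alleles: Sequence[str] | None = None,
) -> GenotypeCounts:
    """Tally per-animal genotype calls for one locus.

    ``records`` is either a DataFrame with columns ``locus`` and ``genotype``
    (plus anything else, typically ``animal_id``) or a plain iterable of
    genotype strings.  With a DataFrame, ``locus`` selects the locus; it must
    be given when the table holds more than one.  ``alleles`` optionally
    restricts the allele alphabet — calls containing any other symbol raise a
    ``ValueError`` naming the offending row.
    """
    if isinstance(records, pd.DataFrame):
        frame = records
        if locus is not None:
            frame = frame[frame["locus"] == locus]
            if frame.empty:
                raise ValueError(f"no rows for locus {locus!r}")
        else:
            found = frame["locus"].unique() if "locus" in frame else ["locus"]
            if len(found) > 1:
                raise ValueError(f"multiple loci present {list(found)}; pass locus=")
            locus = str(found[0])
        calls: Iterable[tuple[object, object]] = frame["genotype"].items()
    else:
        calls = enumerate(records)
        locus = locus or "locus"

    tally: dict[tuple[str, str], int] = {}
    seen: set[str] = set()
    n_missing = 0
    n_rows = 0
    for row_id, raw in calls:
        n_rows += 1
        try:
            pair = _parse_genotype(raw)
        except ValueError as err:
            raise ValueError(f"row {row_id}: {err}") from None
        if pair is None:
            n_missing += 1
            continue
        if alleles is not None:
            for a in pair:
                if a not in alleles:
                    raise ValueError(
                        f"row {row_id}: unknown allele {a!r} (expected {list(alleles)})"
                    )
        seen.update(pair)
        tally[pair] = tally.get(pair, 0) + 1

    if not tally:
        raise ValueError(f"{locus}: zero non-missing genotypes in {n_rows} rows")
    allele_order = tuple(alleles) if alleles is not None else tuple(sorted(seen))
    return GenotypeCounts(locus_id=str(locus), alleles=allele_order,
                          counts=tally, n_missing=n_missing)


def counts_from_mapping(
    locus_id: str,
    genotype_counts: Mapping[str, int],
    alleles: Sequence[str] | None = None,
) -> GenotypeCounts:
    """Build :class:`GenotypeCounts` from ``{"AA": 256, "AG": 150, ...}``."""
    tally: dict[tuple[str, str], int] = {}
    seen: set[str] = set()
    for genotype, count in genotype_counts.items():
        pair = _parse_genotype(genotype)
        if pair is None:
            raise ValueError(f"missing code {genotype!r} is not a genotype class")
        tally[pair] = tally.get(pair, 0) + int(count)
        seen.update(pair)
    allele_order = tuple(alleles) if alleles is not None else tuple(sorted(seen))
    return GenotypeCounts(locus_id=locus_id, alleles=allele_order, counts=tally)


def genotype_frequencies(gc: GenotypeCounts) -> dict[str, float]:
    """Relative genotype frequencies, ``count / N`` per observed class."""
    n = gc.n
    return {_pair_label(pair): count / n for pair, count in sorted(gc.counts.items())}


def allele_frequencies(gc: GenotypeCounts) -> AlleleFrequencies:
    """Allele frequencies by gene counting (each animal contributes 2 genes)."""
    genes: dict[str, int] = {a: 0 for a in gc.alleles}
    for (a, b), count in gc.counts.items():
        genes[a] += count
        genes[b] += count
    total = 2 * gc.n
    return AlleleFrequencies(
        locus_id=gc.locus_id,
        freqs={a: genes[a] / total for a in gc.alleles},
    )


def diversity_indices(af: AlleleFrequencies) -> DiversityIndices:
    """Expected homozygosity, gene diversity, effective allele number, PIC.

    All four are functions of the allele-frequency vector ``p`` alone:
    ``Ho = sum p_i^2``, ``He = 1 - Ho``, ``Ne = 1 / Ho`` and Botstein's
    ``PIC = He - sum_{i<j} 2 p_i^2 p_j^2``.
    """
    p = af.as_array()
    ho = float(np.sum(p**2))
    he = 1.0 - ho
    ne = 1.0 / ho
    cross = sum(2.0 * (p[i] * p[j]) ** 2
                for i, j in itertools.combinations(range(len(p)), 2))
    pic = he - float(cross)
    if pic < 0.25:
        pic_class = "low"
    elif pic <= 0.5:
        pic_class = "moderate"
    else:
        pic_class = "high"
    return DiversityIndices(locus_id=af.locus_id, ho=ho, he=he, ne=ne,
                            pic=pic, pic_class=pic_class)


def hwe_chi_square(gc: GenotypeCounts) -> HWETestResult:
    """Chi-square goodness-of-fit test for Hardy-Weinberg proportions.

    Expected counts are ``N p_i^2`` for homozygotes and ``2 N p_i p_j`` for
    heterozygotes over all ``k(k+1)/2`` genotype classes of the ``k`` observed
    alleles (including classes with zero observed count, e.g. a missing rare
    homozygote).  The statistic sums ``(O - E)^2 / E`` over classes with
    ``E > 0`` and is referred to a chi-square distribution on ``k(k-1)/2``
    degrees of freedom.  Classes with ``E < 5`` are flagged (classical
    validity caveat) but not pooled.
    """
    if len(gc.alleles) < 2:
        raise ValueError(f"{gc.locus_id}: HWE undefined for a monomorphic locus")
    af = allele_frequencies(gc)
    n = gc.n
    k = len(gc.alleles)
    expected: dict[str, float] = {}
    for i, a in enumerate(gc.alleles):
        for b in gc.alleles[i:]:
            pa, pb = af.freqs[a], af.freqs[b]
            pair = tuple(sorted((a, b)))
            e = n * (pa**2 if a == b else 2.0 * pa * pb)
            expected[_pair_label(pair)] = e

    chi2 = 0.0
    low: list[str] = []
    for label, e in expected.items():
        observed = gc.count(label)
        if e <= 0.0:
            if observed > 0:
                raise ValueError(
                    f"{gc.locus_id}: class {label} observed {observed} but expected 0"
                )
            continue
        if e < MIN_EXPECTED:
            low.append(label)
        chi2 += (observed - e) ** 2 / e

    df = k * (k - 1) // 2
    p_value = float(stats.chi2.sf(chi2, df))
    if low:
        warnings.warn(
            f"{gc.locus_id}: expected count < {MIN_EXPECTED:g} for "
            f"{', '.join(low)}; chi-square approximation may be unreliable",
            UserWarning,
            stacklevel=2,
        )
    return HWETestResult(locus_id=gc.locus_id, expected_counts=expected,
                         chi2=float(chi2), df=df, p_value=p_value,
                         low_expected=tuple(low))


def locus_summary(gc: GenotypeCounts, digits: int | None = 2) -> pd.DataFrame:
    """One tidy summary frame per locus, in report style.

    One row per genotype class; the per-locus indices (allele frequencies,
    Ho/He/Ne/PIC, HWE chi-square) are repeated on each row so the frame can
    be written directly as the per-locus summary CSV.  ``digits=None`` keeps
    full precision.
    """
    gfreq = genotype_frequencies(gc)
    af = allele_frequencies(gc)
    div = diversity_indices(af)
    if len(gc.alleles) >= 2:
        hwe = hwe_chi_square(gc)
        chi2, df, p_hwe = hwe.chi2, hwe.df, hwe.p_value
    else:
        chi2 = df = p_hwe = float("nan")

    allele_order = list(gc.alleles)
    rows = []
    for idx, (genotype, freq) in enumerate(gfreq.items()):
        allele = allele_order[idx] if idx < len(allele_order) else ""
        rows.append({
            "locus": gc.locus_id,
            "genotype": genotype,
            "count": gc.count(genotype),
            "genotype_freq": freq,
            "allele": allele,
            "allele_freq": af.freqs[allele] if allele else np.nan,
            "Ho": div.ho,
            "He": div.he,
            "Ne": div.ne,
            "PIC": div.pic,
            "PIC_class": div.pic_class,
            "chi2": chi2,
            "df": df,
            "p_HWE": p_hwe,
        })
    frame = pd.DataFrame(rows)
    if digits is not None:
        numeric = frame.select_dtypes(include=[float]).columns
        frame[numeric] = frame[numeric].round(digits)
    return frame


def read_genotype_csv(path: str) -> pd.DataFrame:
    """Read a per-animal genotype CSV (``animal_id,locus,genotype``)."""
    frame = pd.read_csv(path, dtype=str)
    required = {"animal_id", "locus", "genotype"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    return frame


def read_counts_csv(path: str) -> list[GenotypeCounts]:
    """Read a pre-tallied counts CSV (``locus,genotype,count``)."""
    frame = pd.read_csv(path)
    required = {"locus", "genotype", "count"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    out = []
    for locus, group in frame.groupby("locus", sort=False):
        mapping = dict(zip(group["genotype"], group["count"].astype(int)))
        out.append(counts_from_mapping(str(locus), mapping))
    return out
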