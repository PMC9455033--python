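"""Synthetic data generators mirroring the study's statistical structure.

Every analysis stage in this package can be exercised without animal data:
the generators here produce

* biallelic SNP genotypes for a flock (Hardy-Weinberg proportions, with an
  optional inbreeding-like departure ``F``),
* litter-size records per ewe and parity (1 + Bernoulli twin outcome with
  parity, genotype and interaction effects on the log-odds scale),
* Ct tables for a 13-tissue qPCR panel with tissue-specific fold changes
  and biological + technical noise,
* homologous sequence families evolved along a random tree (together with
  the generating tree, so distance/tree methods can be validated against
  the truth).

Defaults mirror the observed scales of the study population: 433 ewes,
allele frequencies 0.76/0.24 and 0.97/0.03, a twin probability around 0.07
(mean litter size 1.07), triplicate Ct measurements for three animals, and
expression lowest in *longissimus dorsi*.

All generators are deterministic given ``seed``; substreams are spawned per
stage so each generator can be re-run independently of the others.

Alongside the generators sit the calibration experiments that combine a
generator with its analysis stage (type-I error of the HWE test, size and
power of the association model) — the package's own null/recovery
benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import popgen, association
from .qpcr import TISSUES
from .seqchar import DistanceMatrix, Node, leaf_distance_matrix

__all__ = [
    "GenotypeSimSpec",
    "PhenotypeSimSpec",
    "CtSimSpec",
    "TreeSimSpec",
    "gen_genotypes",
    "gen_phenotypes",
    "gen_ct_table",
    "gen_random_tree",
    "evolve_along_tree",
    "gen_homolog_family",
    "hwe_type1_error",
    "association_type1_error",
    "association_power_balanced",
    "DEFAULT_FOLDS",
]

#: default per-tissue fold changes: high in uterus/ovary/lung/spleen, lowest
#: in longissimus dorsi (the qualitative expression pattern being emulated)
DEFAULT_FOLDS: Mapping[str, float] = {
    "hypothalamus": 2.0,
    "hypophysis": 1.6,
    "heart": 1.4,
    "liver": 2.6,
    "spleen": 6.0,
    "lung": 6.5,
    "kidney": 1.9,
    "ovary": 7.2,
    "oviduct": 3.1,
    "uterus": 8.0,
    "rumen": 1.5,
    "duodenum": 2.3,
    "longissimus dorsi": 1.0,
}


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Independent substreams from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# Genotypes


@dataclass(frozen=True)
class GenotypeSimSpec:
    """Biallelic genotype draw: HW proportions with optional departure F.

    Genotype probabilities are ``p^2 + F p q``, ``2 p q (1 - F)``,
    ``q^2 + F p q`` — the one-parameter inbreeding-like family; ``F = 0``
    is exact Hardy-Weinberg, ``F = 1`` removes heterozygotes.
    """

    n_animals: int = 433
    p: float = 0.76
    alleles: tuple[str, str] = ("A", "G")
    f: float = 0.0
    locus_id: str = "g.51537A>G"
    seed: int | None = None

    def genotype_probs(self) -> np.ndarray:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("allele frequency p must be in [0, 1]")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("F must be in [0, 1]")
        p, q, f = self.p, 1.0 - self.p, self.f
        probs = np.array([p * p + f * p * q,
                          2.0 * p * q * (1.0 - f),
                          q * q + f * p * q])
        assert abs(probs.sum() - 1.0) < 1e-12
        return probs


def gen_genotypes(spec: GenotypeSimSpec,
                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-animal genotype records (``animal_id, locus, genotype``)."""
    rng = _rng(rng if rng is not None else spec.seed)
    a, b = spec.alleles
    classes = np.array([a + a, "".join(sorted((a, b))), b + b])
    draws = rng.choice(3, size=spec.n_animals, p=spec.genotype_probs())
    return pd.DataFrame({
        "animal_id": [f"ewe{i:04d}" for i in range(spec.n_animals)],
        "locus": spec.locus_id,
        "genotype": classes[draws],
    })


# ---------------------------------------------------------------------------
# Phenotypes


@dataclass(frozen=True)
class PhenotypeSimSpec:
    """Litter size as 1 + Bernoulli(twin probability).

    The twin probability follows a logistic model:
    ``logit pi = logit(pi0) + parity_effect + genotype_effect + interaction``.
    Effects are on the log-odds scale; a litter-size mean around 1.07 with
    the observed SD (~0.26) corresponds to ``pi0 = 0.07``.
    """

    baseline_twin_prob: float = 0.07
    parity_effects: tuple[float, float, float] = (0.0, 0.0, 0.0)
    genotype_effects: Mapping[str, float] = field(default_factory=dict)
    interaction_effects: Mapping[tuple[int, str], float] = field(default_factory=dict)
    n_parities: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.baseline_twin_prob <= 1.0:
            raise ValueError("baseline twin probability must be in [0, 1]")


def gen_phenotypes(genotypes: pd.DataFrame, spec: PhenotypeSimSpec,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Litter-size records, one row per animal and parity."""
    rng = _rng(rng if rng is not None else spec.seed)
    pi0 = spec.baseline_twin_prob
    if pi0 <= 0.0:
        base_logit = -np.inf
    elif pi0 >= 1.0:
        base_logit = np.inf
    else:
        base_logit = logit(pi0)

    n = len(genotypes)
    k = spec.n_parities
    animal = np.repeat(genotypes["animal_id"].to_numpy(), k)
    genotype = np.repeat(genotypes["genotype"].to_numpy(), k)
    parity = np.tile(np.arange(1, k + 1), n)

    parity_eff = np.asarray(spec.parity_effects, dtype=float)[parity - 1]
    geno_eff = np.array([spec.genotype_effects.get(g, 0.0) for g in genotype])
    inter_eff = (np.array([spec.interaction_effects.get((int(p), g), 0.0)
                           for p, g in zip(parity, genotype)])
                 if spec.interaction_effects else 0.0)
    pi = expit(base_logit + parity_eff + geno_eff + inter_eff)
    litter = 1 + (rng.random(n * k) < pi).astype(int)
    return pd.DataFrame({"animal_id": animal, "parity": parity,
                         "genotype": genotype, "litter_size": litter})


# ---------------------------------------------------------------------------
# Ct tables


@dataclass(frozen=True)
class CtSimSpec:
    """Ct generator: reference at a fixed baseline, target offset by -log2(fold)."""

    tissues: tuple[str, ...] = TISSUES
    fold_changes: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FOLDS))
    target: str = "SMAD5"
    reference: str = "GAPDH"
    reference_baseline: float = 16.0
    target_baseline: float = 22.0
    biological_sd: float = 0.2
    technical_sd: float = 0.05
    n_animals: int = 3
    n_technical: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.biological_sd < 0 or self.technical_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        for tissue in self.tissues:
            fold = self.fold_changes.get(tissue)
            if fold is None or fold <= 0:
                raise ValueError(f"fold change for {tissue!r} must be > 0")


def gen_ct_table(spec: CtSimSpec,
                 rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Ct table (``animal, tissue, gene, replicate, ct``).

    Biological noise is one draw per animal x tissue x gene (shared by its
    technical replicates); technical noise is per well.  With both SDs at 0,
    ``relative_expression`` inverts the specified fold changes exactly.
    """
    rng = _rng(rng if rng is not None else spec.seed)
    rows = []
    for animal in range(1, spec.n_animals + 1):
        for tissue in spec.tissues:
            means = {
                spec.reference: spec.reference_baseline,
                spec.target: (spec.target_baseline
                              - np.log2(spec.fold_changes[tissue])),
            }
            for gene, mean in means.items():
                bio = rng.normal(0.0, spec.biological_sd) if spec.biological_sd else 0.0
                for replicate in range(1, spec.n_technical + 1):
                    tech = (rng.normal(0.0, spec.technical_sd)
                            if spec.technical_sd else 0.0)
                    rows.append((f"animal{animal}", tissue, gene, replicate,
                                 mean + bio + tech))
    return pd.DataFrame(rows, columns=["animal", "tissue", "gene",
                                       "replicate", "ct"])


# ---------------------------------------------------------------------------
# Sequence families and random trees


@dataclass(frozen=True)
class TreeSimSpec:
    """Random tree + per-site substitution process along its branches.

    Branch lengths are uniform on ``branch_length_range`` and are read as
    per-site substitution probabilities (a site changes along a branch with
    that probability, to one of the three other bases uniformly).
    """

    n_taxa: int = 6
    seq_length: int = 500
    branch_length_range: tuple[float, float] = (0.02, 0.2)
    seed: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.branch_length_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("branch lengths are probabilities in [0, 1]")
        if self.n_taxa < 3:
            raise ValueError("need at least 3 taxa")


def gen_random_tree(spec: TreeSimSpec,
                    rng: np.random.Generator | None = None) -> Node:
    """Random binary tree over ``taxon0..taxonN-1`` (root trifurcation)."""
    rng = _rng(rng if rng is not None else spec.seed)
    lo, hi = spec.branch_length_range

    def bl() -> float:
        return float(rng.uniform(lo, hi))

    subtrees = [Node(name=f"taxon{i}", branch_length=bl())
                for i in range(spec.n_taxa)]
    while len(subtrees) > 3:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        joined = Node(branch_length=bl(),
                      children=[subtrees[i], subtrees[j]])
        subtrees = ([s for k, s in enumerate(subtrees) if k not in (i, j)]
                    + [joined])
    root = Node(children=subtrees)
    for child in root.children:
        if child.branch_length is None:
            child.branch_length = bl()
    return root


DNA_BASES = np.array(list("ACGT"))


def evolve_along_tree(tree: Node, seq_length: int,
                      rng: np.random.Generator | None = None
                      ) -> list[tuple[str, str]]:
    """Evolve a random root sequence down ``tree``.

    Each branch length is read as the per-site substitution probability on
    that branch; a substituted site moves to one of the other three bases
    uniformly.  Returns (leaf name, sequence) pairs in traversal order.
    """
    rng = _rng(rng)
    root_seq = rng.integers(0, 4, size=seq_length)
    records: list[tuple[str, str]] = []

    def evolve(node: Node, parent_seq: np.ndarray) -> None:
        seq = parent_seq.copy()
        if node.branch_length:
            hits = rng.random(seq_length) < node.branch_length
            if hits.any():
                shifts = rng.integers(1, 4, size=int(hits.sum()))
                seq[hits] = (seq[hits] + shifts) % 4
        if node.is_leaf:
            records.append((node.name or "", "".join(DNA_BASES[seq])))
        else:
            for child in node.children:
                evolve(child, seq)

    for child in tree.children:
        evolve(child, root_seq)
    return records


def gen_homolog_family(spec: TreeSimSpec,
                       rng: np.random.Generator | None = None
                       ) -> tuple[list[tuple[str, str]], Node]:
    """Evolve a sequence family along a random tree; returns (records, tree)."""
    rng = _rng(rng if rng is not None else spec.seed)
    tree = gen_random_tree(spec, rng)
    return evolve_along_tree(tree, spec.seq_length, rng), tree


# ---------------------------------------------------------------------------
# Calibration experiments (generator + analysis stage)


def hwe_type1_error(
    n_reps: int = 2000,
    spec: GenotypeSimSpec = GenotypeSimSpec(),
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """Empirical size of the HWE chi-square test under exact HW sampling.

    Replicates draw genotype counts from the HW multinomial and run
    :func:`ovigene.popgen.hwe_chi_square`; replicates where any expected
    genotype class falls below the chi-square validity threshold are
    excluded from the rate (and counted).
    """
    if spec.f != 0.0:
        raise ValueError("type-I error is defined under the F=0 null")
    rng = np.random.default_rng(seed)
    probs = spec.genotype_probs()
    a, b = spec.alleles
    labels = (a + a, "".join(sorted((a, b))), b + b)
    counts = rng.multinomial(spec.n_animals, probs, size=n_reps)
    rejected = 0
    used = 0
    excluded = 0
    import warnings as _warnings
    for row in counts:
        mapping = {lab: int(c) for lab, c in zip(labels, row) if c > 0}
        if len({al for lab in mapping for al in lab}) < 2:
            excluded += 1  # monomorphic draw: HWE undefined
            continue
        gc = popgen.counts_from_mapping(spec.locus_id, mapping,
                                        alleles=spec.alleles)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", UserWarning)
            result = popgen.hwe_chi_square(gc)
        if result.low_expected:
            excluded += 1
            continue
        used += 1
        rejected += result.p_value < alpha
    return {"rate": rejected / used if used else float("nan"),
            "n_used": used, "n_excluded": excluded}


def _fixed_genotype_frame(counts: Mapping[str, int]) -> pd.DataFrame:
    rows = []
    i = 0
    for genotype, count in counts.items():
        for _ in range(int(count)):
            rows.append((f"ewe{i:04d}", genotype))
            i += 1
    return pd.DataFrame(rows, columns=["animal_id", "genotype"])


def association_type1_error(
    n_reps: int = 2000,
    genotype_counts: Mapping[str, int] | None = None,
    spec: PhenotypeSimSpec = PhenotypeSimSpec(),
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Genotype-term rejection rate with no genotype effect in the generator.

    The genotype composition is held fixed at the study's class sizes
    (default AA/AG/GG = 256/150/27) so only the phenotypes resample.
    """
    if spec.genotype_effects or spec.interaction_effects:
        raise ValueError("type-I error is defined under a null generator")
    genotype_counts = genotype_counts or {"AA": 256, "AG": 150, "GG": 27}
    genotypes = _fixed_genotype_frame(genotype_counts)
    rng = np.random.default_rng(seed)
    rejections = 0
    import warnings as _warnings
    for _ in range(n_reps):
        pt = gen_phenotypes(genotypes, spec, rng)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", UserWarning)
            result = association.fit_association(pt, alpha=alpha)
        rejections += result.significant
    return rejections / n_reps


def association_power_balanced(
    n_reps: int = 200,
    n_per_cell: int = 20,
    trait_shift: float = 0.3,
    baseline_twin_prob: float = 0.07,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """Effect recovery in a balanced 3-parity x 3-genotype design.

    One genotype class's mean litter size is shifted up by ``trait_shift``
    (default +0.3 lambs, i.e. twin probability 0.07 -> 0.37, expressed on
    the generator's log-odds scale).  Reports the genotype-term rejection
    rate and how often the fitted genotype-mean ordering puts the shifted
    class on top.
    """
    shifted_prob = baseline_twin_prob + trait_shift
    if not 0.0 < shifted_prob < 1.0:
        raise ValueError("shifted twin probability outside (0, 1)")
    effect = float(logit(shifted_prob) - logit(baseline_twin_prob))
    genotypes = ["AA", "AG", "GG"]
    spec = PhenotypeSimSpec(baseline_twin_prob=baseline_twin_prob,
                            genotype_effects={"GG": effect})
    frame = _fixed_genotype_frame(
        {g: 3 * n_per_cell for g in genotypes})  # animals; 3 parities each
    rng = np.random.default_rng(seed)
    detected = 0
    ordered = 0
    for _ in range(n_reps):
        pt = gen_phenotypes(frame, spec, rng)
        result = association.fit_association(pt, alpha=alpha)
        detected += result.significant
        means = result.genotype_summaries.set_index("genotype")["mean"]
        ordered += means.idxmax() == "GG"
    return {"power": detected / n_reps, "ordering_rate": ordered / n_reps}
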