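"""Monte-Carlo simulation of partial NCII populations and evaluation harness.

The generator emulates the study conditions of the method's validation
experiments: two groups of inbred parents with independent biallelic
markers (reference-allele frequency f per marker, default 0.5), a partial
pedigree in which each group-B line is crossed to a small number of
randomly drawn group-A lines, F1 genotypes deduced from the parents, and
phenotypes

    y = mu + sum_i e_i w_i + eps,     eps ~ N(0, sigma^2), sigma^2 = 1

where w_i is the dummy column of the i-th simulated QTL.  Effect sizes
are calibrated from per-QTL heritabilities through

    sigma_G(i)^2 = h_i^2 sigma^2 / (1 - sum_i h_i^2),
    e_i = sqrt(sigma_G(i)^2 / Var(w_i))

with Var the realized population variance of the dummy column, so each
QTL explains exactly its target share of phenotypic variance in the
simulated sample.  The default architecture has 8 QTL: 2 additive,
2 dominant and one each of the aa / ad / da / dd interactions, all
located on markers.

``run_experiment`` repeats simulate -> scan -> match over replicates and
summarizes per-QTL empirical power (LOD above 2.0), mean/SD of the
absolute bias of the effect estimates, and the false positive rate with
denominator (total candidate effects - number of simulated QTL).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .model_matrix import EffectDescriptor, EffectEncoding, effect_count
from .pipeline import ScanConfig, run_scan
from .population import (
    NCIIPopulation,
    ROLE_F1,
    ROLE_PARENT_A,
    ROLE_PARENT_B,
)


@dataclass(frozen=True)
class PopulationStructure:
    """Counts and phenotyping pattern of the simulated population."""

    n_parent_a: int
    n_parent_b: int
    n_f1: int
    phenotype_parents: bool = True
    phenotype_f1: bool = True
    crosses_per_parent_b: int = 2

    def __post_init__(self) -> None:
        if min(self.n_parent_a, self.n_parent_b) < 0 or self.n_f1 < 0:
            raise ValueError("counts must be non-negative")
        if self.n_f1 > 0 and (self.n_parent_a < 2 or self.n_parent_b < 1):
            raise ValueError("F1 simulation needs >= 2 group-A and >= 1 group-B parents")


def parents_only(n_each: int = 300) -> PopulationStructure:
    """All-parents mapping population (no hybrids)."""
    return PopulationStructure(n_each, n_each, 0)


def parents_plus_f1(n_parent_a: int = 150, n_parent_b: int = 150,
                    n_f1: int = 300) -> PopulationStructure:
    """Parents and F1 mixed in the mapping population."""
    return PopulationStructure(n_parent_a, n_parent_b, n_f1)


def f1_only(n_f1: int = 600) -> PopulationStructure:
    """F1-only mapping population (parents genotyped but not phenotyped)."""
    half = (n_f1 + 1) // 2
    return PopulationStructure(half, half, n_f1, phenotype_parents=False)


def sample_size_structure(n: int) -> PopulationStructure:
    """Structure used in the sample-size experiments: n = nB + 2 nB + 2 nB.

    e.g. 400 -> 80 group-B + 160 group-A + 160 F1; each group-B parent is
    crossed to two group-A parents, so the F1 count is exactly 2 nB.
    """
    if n % 5:
        raise ValueError("sample size must be a multiple of 5")
    n_b = n // 5
    return PopulationStructure(2 * n_b, n_b, 2 * n_b)


def breeding_scale_structure() -> PopulationStructure:
    """The 725-individual layout: 298 + 143 parents and 284 hybrids."""
    return PopulationStructure(298, 143, 284)


@dataclass(frozen=True)
class QTLSpec:
    """One simulated QTL: an effect descriptor plus a size.

    Exactly one of ``h2`` (target heritability) or ``effect`` (fixed effect
    magnitude on the coded scale) must be given.
    """

    descriptor: EffectDescriptor
    h2: float | None = None
    effect: float | None = None

    def __post_init__(self) -> None:
        if (self.h2 is None) == (self.effect is None):
            raise ValueError("give exactly one of h2 or effect")
        if self.h2 is not None and not 0 <= self.h2 < 1:
            raise ValueError("h2 must be in [0, 1)")


# default QTL marker placement (indices into the marker panel)
_DEFAULT_QTL_LOCI: tuple[tuple[str, tuple[int, ...]], ...] = (
    ("a", (10,)), ("a", (35,)), ("d", (60,)), ("d", (85,)),
    ("aa", (5, 110)), ("ad", (40, 135)), ("da", (70, 160)), ("dd", (95, 185)),
)


def default_qtl_architecture(h2: float, m: int = 205) -> list[QTLSpec]:
    """The 8-QTL validation architecture: 2 a, 2 d, 1 aa, 1 ad, 1 da, 1 dd.

    All QTL sit on markers; every QTL gets the same heritability ``h2``
    (the sweeps vary this common size).
    """
    specs = []
    for kind, loci in _DEFAULT_QTL_LOCI:
        scaled = tuple(int(j * m / 205) for j in loci)
        desc = (EffectDescriptor(kind, scaled[0]) if len(scaled) == 1
                else EffectDescriptor(kind, *scaled))
        specs.append(QTLSpec(desc, h2=h2))
    return specs


@dataclass
class SimulationSpec:
    """Full parameterization of one simulated dataset."""

    n_markers: int = 205
    allele_freq: float | Sequence[float] = 0.5
    structure: PopulationStructure = field(default_factory=breeding_scale_structure)
    qtl: list[QTLSpec] = field(default_factory=list)
    residual_var: float = 1.0
    mu: float = 0.0

    def __post_init__(self) -> None:
        freqs = self.frequencies()
        if not ((freqs > 0) & (freqs < 1)).all():
            raise ValueError("allele frequencies must lie in (0, 1)")
        total_h2 = sum(q.h2 or 0.0 for q in self.qtl)
        if total_h2 >= 1:
            raise ValueError("sum of QTL heritabilities must be < 1")
        if self.residual_var < 0:
            raise ValueError("residual variance must be >= 0")

    def frequencies(self) -> np.ndarray:
        if np.isscalar(self.allele_freq):
            return np.full(self.n_markers, float(self.allele_freq))
        freqs = np.asarray(self.allele_freq, dtype=float)
        if freqs.size != self.n_markers:
            raise ValueError("allele_freq length must equal n_markers")
        return freqs


@dataclass
class MetricsResult:
    """Power / FPR / bias summary of a simulation experiment."""

    per_qtl: pd.DataFrame  # descriptor, kind, true effect, power, bias stats
    fpr: float
    n_replicates: int
    n_zero_effects: int

    def power_by_category(self) -> dict[str, float]:
        main = self.per_qtl[self.per_qtl["is_main"]]["power"]
        inter = self.per_qtl[~self.per_qtl["is_main"]]["power"]
        return {"main": float(main.median()), "interaction": float(inter.median())}


def simulate_ncii_population(spec: SimulationSpec, seed: int) -> NCIIPopulation:
    """Draw parent genotypes, build the partial pedigree, deduce F1 genotypes.

    Each parent is inbred: at each marker its code is 2 with probability
    equal to the reference-allele frequency, else 0, independently across
    markers and individuals.  Group-B lines are cycled, each crossed to
    ``crosses_per_parent_b`` distinct random group-A lines, until the
    requested F1 count is reached.
    """
    rng = np.random.default_rng(seed)
    st = spec.structure
    freqs = spec.frequencies()
    m = spec.n_markers
    markers = [f"M{j + 1:04d}" for j in range(m)]

    a_ids = [f"A{i + 1:04d}" for i in range(st.n_parent_a)]
    b_ids = [f"B{i + 1:04d}" for i in range(st.n_parent_b)]
    n_parents = st.n_parent_a + st.n_parent_b
    parent_codes = 2.0 * (rng.random((n_parents, m)) < freqs)

    rows = [parent_codes]
    roles = [ROLE_PARENT_A] * st.n_parent_a + [ROLE_PARENT_B] * st.n_parent_b
    ids = a_ids + b_ids

    pedigree_rows = []
    if st.n_f1 > 0:
        f1_codes = np.empty((st.n_f1, m))
        count = 0
        b_cursor = 0
        while count < st.n_f1:
            b = b_ids[b_cursor % st.n_parent_b]
            b_cursor += 1
            mates = rng.choice(st.n_parent_a, size=min(st.crosses_per_parent_b,
                                                       st.n_parent_a), replace=False)
            for a_idx in mates:
                if count >= st.n_f1:
                    break
                f1_id = f"H{count + 1:04d}"
                ca = parent_codes[a_idx]
                cb = parent_codes[st.n_parent_a + (b_cursor - 1) % st.n_parent_b]
                f1_codes[count] = (ca + cb) / 2.0
                pedigree_rows.append({"f1_id": f1_id, "parent_a": a_ids[a_idx],
                                      "parent_b": b})
                ids.append(f1_id)
                roles.append(ROLE_F1)
                count += 1
        rows.append(f1_codes)

    genotypes = pd.DataFrame(np.vstack(rows), index=pd.Index(ids, name="id"),
                             columns=markers)
    return NCIIPopulation(
        genotypes=genotypes,
        roles=pd.Series(roles, index=genotypes.index),
        pedigree=pd.DataFrame(pedigree_rows, columns=["f1_id", "parent_a", "parent_b"]),
        phenotypes=None,
    )


def _phenotyped_ids(population: NCIIPopulation, structure: PopulationStructure):
    ids = []
    if structure.phenotype_parents:
        ids.extend(population.ids_with_role(ROLE_PARENT_A, ROLE_PARENT_B))
    if structure.phenotype_f1:
        ids.extend(population.ids_with_role(ROLE_F1))
    return pd.Index(ids)


def calibrate_qtl_effects(population: NCIIPopulation, spec: SimulationSpec
                          ) -> np.ndarray:
    """Effect magnitudes that hit the target per-QTL genetic variances.

    sigma_G(i)^2 = h_i^2 sigma^2 / (1 - sum h_i^2); the magnitude is
    e_i = sqrt(sigma_G(i)^2 / Var(w_i)) with Var the realized (divisor-n)
    variance of the QTL's dummy column over the phenotyped individuals.
    QTL with a fixed ``effect`` pass through unchanged.
    """
    ids = _phenotyped_ids(population, spec.structure)
    encoding = EffectEncoding.from_population(population, ids=ids)
    total_h2 = sum(q.h2 or 0.0 for q in spec.qtl)
    denom = 1.0 - total_h2
    effects = np.empty(len(spec.qtl))
    for i, q in enumerate(spec.qtl):
        if q.effect is not None:
            effects[i] = q.effect
            continue
        w = encoding.column(q.descriptor)
        var_w = float(w.var())
        if var_w <= 0:
            raise ValueError(
                f"dummy column of {q.descriptor} has zero variance in this "
                "population structure; choose a structure that segregates it")
        sigma_g2 = q.h2 * spec.residual_var / denom
        effects[i] = np.sqrt(sigma_g2 / var_w)
    return effects


def simulate_phenotypes(population: NCIIPopulation, effects: np.ndarray,
                        spec: SimulationSpec, seed: int
                        ) -> tuple[pd.Series, pd.Series]:
    """Phenotypes y = mu + sum e_i w_i + N(0, sigma^2) for the mapped subset.

    Returns (phenotypes, genotypic values), both indexed by individual.
    """
    ids = _phenotyped_ids(population, spec.structure)
    encoding = EffectEncoding.from_population(population, ids=ids)
    g = np.zeros(len(ids))
    for e, q in zip(effects, spec.qtl):
        g += e * encoding.column(q.descriptor)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, np.sqrt(spec.residual_var), size=len(ids))
    y = spec.mu + g + noise
    return (pd.Series(y, index=ids, name="trait"),
            pd.Series(spec.mu + g, index=ids, name="genotypic_value"))


def simulate_dataset(spec: SimulationSpec, seed: int
                     ) -> tuple[NCIIPopulation, dict]:
    """One full draw: population + phenotypes + truth record."""
    population = simulate_ncii_population(spec, seed)
    effects = calibrate_qtl_effects(population, spec)
    # derived seed for the phenotype noise, decoupled from the genotype draw
    y, g = simulate_phenotypes(population, effects, spec, seed=(seed + 7919) % 2**31)
    population = population.with_phenotypes(y.reindex(population.individuals))
    total_h2 = sum(q.h2 or 0.0 for q in spec.qtl)
    truth = {
        "mu": spec.mu,
        "sigma2": spec.residual_var,
        "qtl": [
            {
                "descriptor": q.descriptor,
                "h2": q.h2,
                "sigma2_g": (None if q.h2 is None
                             else q.h2 * spec.residual_var / (1.0 - total_h2)),
                "effect": float(e),
            }
            for q, e in zip(spec.qtl, effects)
        ],
        "genotypic_values": g,
    }
    return population, truth


def run_experiment(spec: SimulationSpec, scan_config: ScanConfig | None = None,
                   replicates: int = 100, base_seed: int = 1) -> MetricsResult:
    """Simulate -> scan -> match over replicates; summarize power/FPR/bias.

    A simulated QTL counts as detected in a replicate when its exact effect
    descriptor appears in the final scan report (every reported effect has
    LOD >= the scan threshold).  Replicate seeds derive deterministically
    from ``base_seed`` + replicate index.
    """
    scan_config = scan_config or ScanConfig()
    n_true = len(spec.qtl)
    n_total = effect_count(spec.n_markers)
    n_zero = n_total - n_true
    detected = np.zeros(n_true, dtype=int)
    biases: list[list[float]] = [[] for _ in range(n_true)]
    fpr_reps = []
    for rep in range(replicates):
        seed = (base_seed + rep) % 2**31
        population, truth = simulate_dataset(spec, seed)
        records = run_scan(population, scan_config)
        found = {r.descriptor: r for r in records}
        for i, q in enumerate(truth["qtl"]):
            rec = found.pop(q["descriptor"], None)
            if rec is not None:
                detected[i] += 1
                biases[i].append(abs(rec.effect - q["effect"]))
        fpr_reps.append(len(found) / n_zero)
    rows = []
    for i, q in enumerate(spec.qtl):
        b = np.asarray(biases[i], dtype=float)
        rows.append({
            "kind": q.descriptor.kind,
            "descriptor": q.descriptor,
            "is_main": q.descriptor.is_main,
            "h2": q.h2,
            "power": detected[i] / replicates,
            "bias_mean": float(b.mean()) if b.size else float("nan"),
            "bias_sd": float(b.std()) if b.size else float("nan"),
            "n_detected": int(detected[i]),
        })
    return MetricsResult(per_qtl=pd.DataFrame(rows), fpr=float(np.mean(fpr_reps)),
                         n_replicates=replicates, n_zero_effects=n_zero)
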