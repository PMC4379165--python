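"""Hybrid prediction and combining-ability analysis for partial NCII designs.

In a partial design only a subset of the |A| x |B| crosses was realized,
so classical GCA/SCA analysis cannot be computed from phenotypes alone.
The detected QTL fill the gap: for every cross (i, j) the F1 genotype at
each QTL marker follows from the inbred parents (parental mean code), and
the genotypic value is v_ij = mu-hat + sum_k w_k(i, j) * gamma-hat_k.
Observed F1 phenotypes replace predictions where the cross exists (the
default).  On the completed table,

    GCA_i  = row mean - grand mean        (group-A parents)
    GCA_j  = column mean - grand mean     (group-B parents)
    SCA_ij = v_ij - grand mean - GCA_i - GCA_j

and elite parents / crosses are ranked by GCA and by the cross value
("BV", with SCA reported alongside).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model_matrix import EffectDescriptor
from .pipeline import QTLRecord
from .population import (
    NCIIPopulation,
    ROLE_PARENT_A,
    ROLE_PARENT_B,
    allele_frequencies,
)

logger = logging.getLogger(__name__)


@dataclass
class HybridTable:
    """Complete hybrid-value table: rows = group-A parents, cols = group-B."""

    values: pd.DataFrame
    provenance: pd.DataFrame  # "observed" | "predicted" per cell


@dataclass
class CombiningAbilities:
    grand_mean: float
    gca_a: pd.Series
    gca_b: pd.Series
    sca: pd.DataFrame
    bv: pd.DataFrame  # the table values themselves


def _parent_allele_prob(codes: np.ndarray, freq: float) -> np.ndarray:
    """Per-parent probability of transmitting the reference allele.

    Inbred codes 0/2 give 0/1; a missing code falls back to the
    population allele frequency (flagged by the caller).
    """
    p = codes / 2.0
    return np.where(np.isnan(p), freq, p)


def predict_hybrid_table(population: NCIIPopulation,
                         qtl: Sequence[QTLRecord],
                         mu: float | None = None,
                         use_observed: bool = True) -> HybridTable:
    """Predict genotypic values for every (parentA, parentB) combination.

    ``mu`` is the fitted population mean of the scan (defaults to the mean
    observed phenotype).  With ``use_observed`` the phenotype of a realized
    cross replaces its prediction and the cell is flagged "observed".
    """
    a_ids = list(population.ids_with_role(ROLE_PARENT_A))
    b_ids = list(population.ids_with_role(ROLE_PARENT_B))
    if not a_ids or not b_ids:
        raise ValueError("population must contain both parent groups")
    if mu is None:
        mu = float(population.phenotypes.dropna().mean())

    freq = allele_frequencies(population, roles=(ROLE_PARENT_A, ROLE_PARENT_B))
    geno_a = population.genotypes.loc[a_ids]
    geno_b = population.genotypes.loc[b_ids]

    # per needed marker: x (additive) and z (heterozygosity prob) for each cross
    needed = sorted({j for rec in qtl for j in rec.descriptor.loci()})
    marker_names = list(population.markers)
    x_cols: dict[int, np.ndarray] = {}
    z_cols: dict[int, np.ndarray] = {}
    for j in needed:
        name = marker_names[j]
        ca = geno_a[name].to_numpy(dtype=float)
        cb = geno_b[name].to_numpy(dtype=float)
        if np.isnan(ca).any() or np.isnan(cb).any():
            logger.warning("missing parent genotype at QTL marker %s; "
                           "imputed from the parental allele frequency", name)
        pa = _parent_allele_prob(ca, float(freq[name]))
        pb = _parent_allele_prob(cb, float(freq[name]))
        # expected F1 code = pa + pb alleles -> x = pa + pb - 1
        x_cols[j] = pa[:, None] + pb[None, :] - 1.0
        z_cols[j] = pa[:, None] * (1.0 - pb[None, :]) + (1.0 - pa[:, None]) * pb[None, :]

    v = np.full((len(a_ids), len(b_ids)), mu, dtype=float)
    for rec in qtl:
        d = rec.descriptor
        if d.is_main:
            w = x_cols[d.locus1] if d.kind == "a" else z_cols[d.locus1]
        else:
            left = x_cols[d.locus1] if d.kind[0] == "a" else z_cols[d.locus1]
            right = x_cols[d.locus2] if d.kind[1] == "a" else z_cols[d.locus2]
            w = left * right
        v = v + w * rec.effect

    values = pd.DataFrame(v, index=pd.Index(a_ids, name="parentA"),
                          columns=pd.Index(b_ids, name="parentB"))
    provenance = pd.DataFrame("predicted", index=values.index, columns=values.columns)
    if use_observed:
        for _, row in population.pedigree.iterrows():
            obs = population.phenotypes.get(row["f1_id"], np.nan)
            if pd.notna(obs):
                values.loc[row["parent_a"], row["parent_b"]] = float(obs)
                provenance.loc[row["parent_a"], row["parent_b"]] = "observed"
    return HybridTable(values=values, provenance=provenance)


def combining_abilities(table: HybridTable | pd.DataFrame) -> CombiningAbilities:
    """Two-way main-effect decomposition of a complete hybrid table."""
    values = table.values if isinstance(table, HybridTable) else table
    if isinstance(values, np.ndarray):
        values = pd.DataFrame(values)
    if values.isna().any().any():
        raise ValueError("hybrid table must be complete")
    grand = float(values.to_numpy().mean())
    gca_a = values.mean(axis=1) - grand
    gca_b = values.mean(axis=0) - grand
    sca = values - grand - np.add.outer(gca_a.to_numpy(), gca_b.to_numpy())
    return CombiningAbilities(grand_mean=grand, gca_a=gca_a, gca_b=gca_b,
                              sca=sca, bv=values)


def rank_elites(ca: CombiningAbilities, top: int = 10
                ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Top parents by GCA and top crosses by BV (SCA annotated).

    Returns (group-A parents, group-B parents, crosses); ties resolve by id.
    """
    if top < 1:
        raise ValueError("top must be >= 1")

    def _rank_series(s: pd.Series, id_col: str) -> pd.DataFrame:
        df = s.rename("gca").reset_index()
        df.columns = [id_col, "gca"]
        df = df.sort_values(["gca", id_col], ascending=[False, True],
                            kind="mergesort").head(top)
        return df.reset_index(drop=True)

    top_a = _rank_series(ca.gca_a, "parentA")
    top_b = _rank_series(ca.gca_b, "parentB")

    stacked = ca.bv.stack().rename("bv").reset_index()
    stacked.columns = ["parentA", "parentB", "bv"]
    stacked["sca"] = [ca.sca.loc[a, b] for a, b in zip(stacked["parentA"],
                                                       stacked["parentB"])]
    crosses = stacked.sort_values(["bv", "parentA", "parentB"],
                                  ascending=[False, True, True],
                                  kind="mergesort").head(top)
    return top_a, top_b, crosses.reset_index(drop=True)
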