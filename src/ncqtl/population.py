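"""Data model and I/O for partial NCII mating-design populations.

A North Carolina design II (NCII) population consists of two groups of
inbred parents -- here called group A (e.g. cytoplasmic male-sterile
lines) and group B (e.g. fertility-restorer lines) -- together with the
F1 hybrids of a subset of the |A| x |B| possible crosses ("partial"
design).  Genotypes are biallelic and coded as the number of copies of
the reference allele (0, 1 or 2); F1 genotypes are fully determined by
the inbred parents and can be deduced rather than assayed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

ROLE_PARENT_A = "parentA"
ROLE_PARENT_B = "parentB"
ROLE_F1 = "F1"
ROLES = (ROLE_PARENT_A, ROLE_PARENT_B, ROLE_F1)

_VALID_CODES = (0.0, 1.0, 2.0)


class PopulationError(ValueError):
    """Raised when a population violates a structural invariant."""


def _check_codes(genotypes: pd.DataFrame) -> None:
    values = genotypes.to_numpy(dtype=float)
    finite = values[~np.isnan(values)]
    if finite.size and not np.isin(finite, _VALID_CODES).all():
        bad = sorted(set(finite[~np.isin(finite, _VALID_CODES)]))
        raise PopulationError(f"genotype codes outside {{0,1,2,NA}}: {bad}")


@dataclass
class NCIIPopulation:
    """A partial NCII population: genotypes, roles, pedigree and phenotypes.

    Parameters
    ----------
    genotypes : DataFrame, individuals x markers, float codes in {0,1,2},
        NaN for missing.
    roles : Series mapping individual id -> role in
        {"parentA", "parentB", "F1"}.
    pedigree : DataFrame with columns (f1_id, parent_a, parent_b); one row
        per realized cross.
    phenotypes : Series of trait values indexed by individual id; NaN for
        unphenotyped individuals.  Individuals without a phenotype are kept
        but excluded from mapping.
    trait : name of the phenotype (reporting only).
    """

    genotypes: pd.DataFrame
    roles: pd.Series
    pedigree: pd.DataFrame
    phenotypes: pd.Series | None = None
    trait: str = "trait"
    non_inbred_parent: str = "warn"  # "warn" | "error" | "ignore"

    def __post_init__(self) -> None:
        self.genotypes = self.genotypes.astype(float)
        if self.genotypes.index.has_duplicates:
            raise PopulationError("duplicate individual ids in genotypes")
        if self.genotypes.columns.has_duplicates:
            raise PopulationError("duplicate marker names in genotypes")
        _check_codes(self.genotypes)
        self.roles = self.roles.reindex(self.genotypes.index)
        if self.roles.isna().any():
            missing = list(self.roles.index[self.roles.isna()])
            raise PopulationError(f"individuals without a role: {missing}")
        bad_roles = set(self.roles.unique()) - set(ROLES)
        if bad_roles:
            raise PopulationError(f"unknown roles: {sorted(bad_roles)}")
        if self.pedigree is None or len(self.pedigree) == 0:
            self.pedigree = pd.DataFrame(columns=["f1_id", "parent_a", "parent_b"])
        self.pedigree = self.pedigree[["f1_id", "parent_a", "parent_b"]].astype(str)
        self._check_pedigree()
        self._check_inbred_parents()
        if self.phenotypes is None:
            self.phenotypes = pd.Series(np.nan, index=self.genotypes.index)
        extra = self.phenotypes.index.difference(self.genotypes.index)
        if len(extra):
            raise PopulationError(f"phenotyped ids absent from genotypes: {list(extra)}")
        values = self.phenotypes.to_numpy(dtype=float)
        if np.isinf(values).any():
            raise PopulationError("non-finite phenotype values")
        self.phenotypes = self.phenotypes.reindex(self.genotypes.index).astype(float)

    # -- invariants ------------------------------------------------------

    def _check_pedigree(self) -> None:
        ids = set(self.genotypes.index)
        for _, row in self.pedigree.iterrows():
            for col, role in (("parent_a", ROLE_PARENT_A), ("parent_b", ROLE_PARENT_B)):
                pid = row[col]
                if pid not in ids:
                    raise PopulationError(f"pedigree references unknown parent {pid!r}")
                if self.roles[pid] != role:
                    raise PopulationError(
                        f"pedigree parent {pid!r} has role {self.roles[pid]!r}, expected {role!r}"
                    )
            if row["f1_id"] not in ids:
                raise PopulationError(f"pedigree references unknown F1 {row['f1_id']!r}")
            if self.roles[row["f1_id"]] != ROLE_F1:
                raise PopulationError(f"pedigree F1 {row['f1_id']!r} does not have role F1")
        n_a = int((self.roles == ROLE_PARENT_A).sum())
        n_b = int((self.roles == ROLE_PARENT_B).sum())
        if len(self.pedigree) > n_a * n_b:
            raise PopulationError("more crosses than |parentA| x |parentB| combinations")

    def _check_inbred_parents(self) -> None:
        if self.non_inbred_parent == "ignore":
            return
        parent_mask = self.roles.isin([ROLE_PARENT_A, ROLE_PARENT_B])
        parents = self.genotypes.loc[parent_mask]
        het = (parents == 1.0).any(axis=1)
        if het.any():
            offenders = list(parents.index[het])
            msg = f"non-inbred parents (heterozygous codes): {offenders}"
            if self.non_inbred_parent == "error":
                raise PopulationError(msg)
            warnings.warn(msg, UserWarning, stacklevel=3)

    # -- convenience -----------------------------------------------------

    @property
    def individuals(self) -> pd.Index:
        return self.genotypes.index

    @property
    def markers(self) -> pd.Index:
        return self.genotypes.columns

    def ids_with_role(self, *roles: str) -> pd.Index:
        return self.genotypes.index[self.roles.isin(roles)]

    def mapped_ids(self) -> pd.Index:
        """Individuals that enter mapping: those with a phenotype."""
        return self.genotypes.index[self.phenotypes.notna()]

    def with_phenotypes(self, phenotypes: pd.Series, trait: str | None = None) -> "NCIIPopulation":
        return replace(self, phenotypes=phenotypes, trait=trait or self.trait)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_population(
    genotype_table: str,
    phenotype_table: str | None = None,
    pedigree_table: str | None = None,
    trait: str | None = None,
    non_inbred_parent: str = "warn",
) -> NCIIPopulation:
    """Load a population from comma-delimited text tables.

    ``genotypes.csv``: columns ``id,role,<marker1>,...`` with codes 0/1/2 and
    empty cells for missing.  ``phenotypes.csv``: ``id,<trait>``.
    ``pedigree.csv``: ``f1_id,parentA_id,parentB_id``.
    """
    geno = pd.read_csv(genotype_table, dtype={"id": str, "role": str})
    if geno.columns[0] != "id" or geno.columns[1] != "role":
        raise PopulationError("genotype table must start with columns 'id,role'")
    if geno["id"].duplicated().any():
        dup = list(geno["id"][geno["id"].duplicated()])
        raise PopulationError(f"duplicate individual ids: {dup}")
    geno = geno.set_index("id")
    roles = geno["role"]
    codes = geno.drop(columns=["role"]).astype(float)

    phenotypes = None
    trait_name = trait or "trait"
    if phenotype_table is not None:
        pheno = pd.read_csv(phenotype_table, dtype={"id": str})
        if pheno["id"].duplicated().any():
            raise PopulationError("duplicate ids in phenotype table")
        pheno = pheno.set_index("id")
        trait_name = trait or pheno.columns[0]
        phenotypes = pheno[trait_name].astype(float).reindex(codes.index)

    pedigree = None
    if pedigree_table is not None:
        pedigree = pd.read_csv(pedigree_table, dtype=str)
        pedigree.columns = ["f1_id", "parent_a", "parent_b"]

    return NCIIPopulation(
        genotypes=codes,
        roles=roles,
        pedigree=pedigree,
        phenotypes=phenotypes,
        trait=trait_name,
        non_inbred_parent=non_inbred_parent,
    )


def write_population(population: NCIIPopulation, genotype_table: str,
                     phenotype_table: str | None = None,
                     pedigree_table: str | None = None) -> None:
    """Write a population back to the delimited-text layout of ``load_population``."""
    out = population.genotypes.copy()
    out.insert(0, "role", population.roles)
    # keep the code domain integral in text form; missing stays empty
    formatted = out.copy()
    for col in population.markers:
        formatted[col] = out[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
    formatted.to_csv(genotype_table, index_label="id")
    if phenotype_table is not None:
        pheno = population.phenotypes.dropna().rename(population.trait)
        pheno.to_csv(phenotype_table, index_label="id")
    if pedigree_table is not None:
        population.pedigree.to_csv(pedigree_table, index=False)


# ---------------------------------------------------------------------------
# F1 deduction and allele frequencies
# ---------------------------------------------------------------------------

def deduce_f1_genotypes(population: NCIIPopulation) -> NCIIPopulation:
    """Deduce F1 genotypes from their inbred parents.

    The F1 code at a marker is the parental mean, (code_A + code_B) / 2;
    a missing parent code propagates to a missing F1 code.  Explicitly
    provided F1 codes are kept and checked for consistency with the
    deduction.  A heterozygous parent code (1) is an error: the cross
    would segregate and the F1 genotype would not be unique.
    """
    geno = population.genotypes.copy()
    for _, row in population.pedigree.iterrows():
        a = geno.loc[row["parent_a"]].to_numpy()
        b = geno.loc[row["parent_b"]].to_numpy()
        for pid, codes in ((row["parent_a"], a), (row["parent_b"], b)):
            het = np.where(codes == 1.0)[0]
            if het.size:
                marker = population.markers[het[0]]
                raise PopulationError(
                    f"parent {pid!r} is heterozygous at marker {marker!r}; "
                    "F1 genotype cannot be deduced"
                )
        deduced = (a + b) / 2.0
        existing = geno.loc[row["f1_id"]].to_numpy()
        provided = ~np.isnan(existing)
        conflict = provided & ~np.isnan(deduced) & (existing != deduced)
        if conflict.any():
            marker = population.markers[np.where(conflict)[0][0]]
            raise PopulationError(
                f"F1 {row['f1_id']!r} genotype at {marker!r} conflicts with parental deduction"
            )
        merged = np.where(provided, existing, deduced)
        geno.loc[row["f1_id"]] = merged
    return replace(population, genotypes=geno)


def allele_frequencies(population: NCIIPopulation,
                       roles: Iterable[str] | None = None,
                       ids: Sequence[str] | None = None) -> pd.Series:
    """Reference-allele frequency per marker over a subset of individuals.

    frequency = sum of codes / (2 x number of non-missing codes).  Markers
    with no non-missing code in the subset get NaN (flagged undefined).
    """
    if ids is not None:
        sub = population.genotypes.loc[list(ids)]
    elif roles is not None:
        sub = population.genotypes.loc[population.roles.isin(list(roles))]
    else:
        sub = population.genotypes
    values = sub.to_numpy(dtype=float)
    n_obs = np.sum(~np.isnan(values), axis=0)
    totals = np.nansum(values, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_obs > 0, totals / (2.0 * n_obs), np.nan)
    return pd.Series(freq, index=population.markers, name="allele_frequency")
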