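"""Design-matrix encoding for the full additive/dominance/epistasis model.

Each marker j contributes an additive dummy x in {-1, 0, 1} (code - 1)
and a dominance dummy z in {0, 1} (heterozygote indicator).  Every
ordered pair j < k contributes four statistical interaction columns:
aa = x_j*x_k, ad = x_j*z_k, da = z_j*x_k and dd = z_j*z_k.  With m
markers the full model holds 2m main-effect columns plus 2m(m-1)
interaction columns; the model matrix is never materialized in full --
columns are built on demand from the per-marker encodings.

Missing genotypes are mean-imputed on each scale when a dense column is
requested (additive: 2f - 1 for reference-allele frequency f; dominance:
the observed heterozygote frequency) and left as NaN in the raw encoding
used by the screening stage, which excludes missing individuals per test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MAIN_KINDS = ("a", "d")
INTERACTION_KINDS = ("aa", "ad", "da", "dd")
KINDS = MAIN_KINDS + INTERACTION_KINDS


@dataclass(frozen=True)
class EffectDescriptor:
    """One candidate effect: a kind and one or two marker indices.

    ``ad(j, k)`` is additive at locus1 times dominance at locus2 and is a
    different effect from ``da(j, k)``; interactions require locus1 < locus2.
    """

    kind: str
    locus1: int
    locus2: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if self.kind in MAIN_KINDS:
            if self.locus2 is not None:
                raise ValueError(f"main effect {self.kind!r} takes a single locus")
        else:
            if self.locus2 is None:
                raise ValueError(f"interaction {self.kind!r} needs two loci")
            if not self.locus1 < self.locus2:
                raise ValueError("interaction loci must satisfy locus1 < locus2")

    @property
    def is_main(self) -> bool:
        return self.kind in MAIN_KINDS

    def loci(self) -> tuple[int, ...]:
        return (self.locus1,) if self.locus2 is None else (self.locus1, self.locus2)

    def name(self, markers: Sequence[str]) -> str:
        """Report label, e.g. ``a:CB10597C`` or ``ad:xy2b×CB10343B``."""
        if self.is_main:
            return f"{self.kind}:{markers[self.locus1]}"
        return f"{self.kind}:{markers[self.locus1]}×{markers[self.locus2]}"


def effect_count(m: int) -> int:
    """Closed-form size of the full model: 2m main + 2m(m-1) interactions."""
    return 2 * m + 2 * m * (m - 1)


def enumerate_effects(m: int) -> list[EffectDescriptor]:
    """All candidate effects in canonical order.

    Order: a then d per marker, followed by (aa, ad, da, dd) for each
    ordered pair j < k, pairs in lexicographic order.
    """
    if m < 1:
        raise ValueError("need at least one marker")
    effects: list[EffectDescriptor] = []
    for j in range(m):
        effects.append(EffectDescriptor("a", j))
        effects.append(EffectDescriptor("d", j))
    for j in range(m - 1):
        for k in range(j + 1, m):
            for kind in INTERACTION_KINDS:
                effects.append(EffectDescriptor(kind, j, k))
    return effects


def descriptor_order_index(descriptor: EffectDescriptor, m: int) -> int:
    """Position of a descriptor in ``enumerate_effects(m)`` without enumerating."""
    if descriptor.is_main:
        return 2 * descriptor.locus1 + MAIN_KINDS.index(descriptor.kind)
    j, k = descriptor.locus1, descriptor.locus2
    pair_rank = j * m - j * (j + 1) // 2 + (k - j - 1)
    return 2 * m + 4 * pair_rank + INTERACTION_KINDS.index(descriptor.kind)


def encode_marker(codes: np.ndarray, impute: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Encode genotype codes into (additive x, dominance z) dummy columns.

    x = code - 1 in {-1, 0, 1}; z = 1 for heterozygotes else 0.  Missing
    codes become the column mean of the observed encodings when ``impute``
    is on, otherwise NaN.
    """
    codes = np.asarray(codes, dtype=float)
    x = codes - 1.0
    z = np.where(codes == 1.0, 1.0, 0.0)
    missing = np.isnan(codes)
    z[missing] = np.nan
    if impute and missing.any():
        if missing.all():
            x[:] = 0.0
            z[:] = 0.0
        else:
            x[missing] = np.nanmean(x)
            z[missing] = np.nanmean(z)
    return x, z


class EffectEncoding:
    """Per-marker dummy encodings of a set of individuals, with column access.

    ``X``/``Z`` are the imputed dense encodings used to build model-matrix
    columns; ``X_raw``/``Z_raw`` keep NaN at missing genotypes for the
    screening stage.
    """

    def __init__(self, genotypes: pd.DataFrame):
        codes = genotypes.to_numpy(dtype=float)
        self.ids = genotypes.index
        self.markers = list(genotypes.columns)
        self.n, self.m = codes.shape
        self.X_raw = codes - 1.0
        self.Z_raw = np.where(codes == 1.0, 1.0, 0.0)
        missing = np.isnan(codes)
        self.Z_raw[missing] = np.nan
        self.X = self.X_raw.copy()
        self.Z = self.Z_raw.copy()
        if missing.any():
            col_all_missing = missing.all(axis=0)
            with np.errstate(invalid="ignore"):
                x_mean = np.where(col_all_missing, 0.0, np.nanmean(self.X_raw, axis=0))
                z_mean = np.where(col_all_missing, 0.0, np.nanmean(self.Z_raw, axis=0))
            rows, cols = np.where(missing)
            self.X[rows, cols] = x_mean[cols]
            self.Z[rows, cols] = z_mean[cols]

    @classmethod
    def from_population(cls, population, ids: Sequence[str] | None = None) -> "EffectEncoding":
        geno = population.genotypes
        if ids is not None:
            geno = geno.loc[list(ids)]
        return cls(geno)

    def column(self, descriptor: EffectDescriptor) -> np.ndarray:
        """Dense model-matrix column for one effect (imputed encoding)."""
        j = descriptor.locus1
        if descriptor.kind == "a":
            return self.X[:, j].copy()
        if descriptor.kind == "d":
            return self.Z[:, j].copy()
        k = descriptor.locus2
        left = self.X[:, j] if descriptor.kind[0] == "a" else self.Z[:, j]
        right = self.X[:, k] if descriptor.kind[1] == "a" else self.Z[:, k]
        return left * right

    def columns(self, descriptors: Iterable[EffectDescriptor]) -> np.ndarray:
        descriptors = list(descriptors)
        out = np.empty((self.n, len(descriptors)))
        for i, desc in enumerate(descriptors):
            out[:, i] = self.column(desc)
        return out

    def subset(self, index: np.ndarray) -> "EffectEncoding":
        """Encoding restricted to a boolean/positional row subset (no re-imputation)."""
        new = object.__new__(EffectEncoding)
        new.ids = self.ids[index]
        new.markers = self.markers
        new.X_raw = self.X_raw[index]
        new.Z_raw = self.Z_raw[index]
        new.X = self.X[index]
        new.Z = self.Z[index]
        new.n, new.m = new.X.shape
        return new
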