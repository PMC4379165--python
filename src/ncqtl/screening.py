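"""Bulked-segregant (extreme-group) chi-square screening of candidate effects.

The full model for m markers holds 2m + 2m(m-1) candidate effects -- far
more than can be fitted jointly.  Screening compares the distribution of
each effect's dummy column between the highest- and lowest-phenotype
tails of the population with a Pearson chi-square test of independence
(no continuity correction).  The contingency rows are the distinct
observed values of the effect column (so interaction tables use the
product-coded classes), giving df = levels - 1: additive-style columns
have up to 3 levels (df <= 2), dominance-style columns 2 levels (df = 1).

All 84,050 candidate tests for m = 205 are computed at once from a
handful of indicator-matrix products, so a full screening pass costs a
few milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model_matrix import (
    INTERACTION_KINDS,
    EffectDescriptor,
    EffectEncoding,
    descriptor_order_index,
)


@dataclass(frozen=True)
class ScreenResult:
    """Chi-square screening outcome for one candidate effect."""

    descriptor: EffectDescriptor
    chi2: float
    df: int
    p: float
    untestable: bool = False


class ScreeningError(ValueError):
    pass


# ---------------------------------------------------------------------------
# extreme-group selection
# ---------------------------------------------------------------------------

def select_extremes(phenotypes: pd.Series, fraction: float = 0.10
                    ) -> tuple[list[str], list[str]]:
    """Split off the highest and lowest phenotype tails.

    Each tail holds floor(fraction * n) individuals.  Individuals are
    ordered by (value, id) ascending; the low tail takes the first k and
    the high tail the last k, so boundary ties resolve by id and the two
    tails are always disjoint (requiring 2k <= n).

    Returns (high ids, low ids).
    """
    if not 0 < fraction <= 0.5:
        raise ScreeningError("tail fraction must be in (0, 0.5]")
    values = phenotypes.dropna()
    n = len(values)
    if n < 2:
        raise ScreeningError("need at least 2 phenotyped individuals")
    k = int(np.floor(fraction * n))
    if k < 1:
        raise ScreeningError(f"tail fraction {fraction} selects no individuals at n={n}")
    if 2 * k > n:
        raise ScreeningError("tails overlap: fraction too large for the sample size")
    order = values.to_frame("y").assign(_id=values.index.astype(str))
    order = order.sort_values(["y", "_id"], kind="mergesort")
    low = list(order.index[:k])
    high = list(order.index[-k:])
    return high, low


# ---------------------------------------------------------------------------
# single-effect Pearson chi-square (scalar reference path)
# ---------------------------------------------------------------------------

def chi2_independence(column: np.ndarray, in_high: np.ndarray,
                      descriptor: EffectDescriptor | None = None) -> ScreenResult:
    """Pearson chi-square test of independence for one effect column.

    ``column`` holds the effect dummy values for the pooled extreme
    individuals (NaN = missing genotype, excluded); ``in_high`` flags
    membership in the high tail.  Rows of the L x 2 table are the distinct
    observed column values; zero-margin levels are dropped.  A single
    observed level is untestable and reported with p = 1.
    """
    column = np.asarray(column, dtype=float)
    in_high = np.asarray(in_high, dtype=bool)
    keep = ~np.isnan(column)
    column, in_high = column[keep], in_high[keep]
    levels = np.unique(column)
    if levels.size < 2 or in_high.all() or not in_high.any():
        return ScreenResult(descriptor, 0.0, 0, 1.0, untestable=True)
    table = np.zeros((levels.size, 2))
    for i, lv in enumerate(levels):
        at = column == lv
        table[i, 0] = np.sum(at & in_high)
        table[i, 1] = np.sum(at & ~in_high)
    chi2, _, df, _ = stats.chi2_contingency(table, correction=False)
    p = float(stats.chi2.sf(chi2, df))
    return ScreenResult(descriptor, float(chi2), int(df), p)


# ---------------------------------------------------------------------------
# vectorized screening of every candidate effect
# ---------------------------------------------------------------------------

def _pearson_from_counts(high: np.ndarray, low: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Chi-square for a batch of L x 2 tables given per-level counts.

    ``high``/``low``: (n_effects, L) count arrays; levels with zero total
    are dropped per effect.  Returns (chi2, df, p, untestable).
    """
    high = np.asarray(high, dtype=float)
    low = np.asarray(low, dtype=float)
    t = high + low
    H = high.sum(axis=1, keepdims=True)
    L = low.sum(axis=1, keepdims=True)
    N = H + L
    present = t > 0
    df = present.sum(axis=1) - 1
    untestable = (df < 1) | (H[:, 0] == 0) | (L[:, 0] == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        eh = t * H / N
        el = t * L / N
        terms = np.where(present & (eh > 0), (high - eh) ** 2 / eh, 0.0)
        terms += np.where(present & (el > 0), (low - el) ** 2 / el, 0.0)
    chi2 = terms.sum(axis=1)
    chi2[untestable] = 0.0
    df = np.maximum(df, 1)
    p = stats.chi2.sf(chi2, df)
    p[untestable] = 1.0
    return chi2, df, p, untestable


def _group_indicators(enc: EffectEncoding, rows: np.ndarray) -> dict[str, np.ndarray]:
    X = enc.X_raw[rows]
    Z = enc.Z_raw[rows]
    valid = ~np.isnan(X)
    return {
        "P": (X == 1.0).astype(float),
        "N": (X == -1.0).astype(float),
        "H": np.where(np.isnan(Z), 0.0, Z),
        "V": valid.astype(float),
        "X": X,
        "Z": Z,
    }


def screen_all_effects(encoding: EffectEncoding, high_ids, low_ids) -> pd.DataFrame:
    """Chi-square screen of every candidate effect in one vectorized pass.

    Returns a DataFrame indexed by canonical effect order with columns
    (kind, locus1, locus2, chi2, df, p, untestable, is_main).
    """
    id_pos = {str(i): pos for pos, i in enumerate(encoding.ids)}
    hi = np.array([id_pos[str(i)] for i in high_ids], dtype=int)
    lo = np.array([id_pos[str(i)] for i in low_ids], dtype=int)
    g_hi = _group_indicators(encoding, hi)
    g_lo = _group_indicators(encoding, lo)
    m = encoding.m
    iu_j, iu_k = np.triu_indices(m, k=1)
    n_pairs = iu_j.size

    frames = []

    # main effects: per-marker level counts
    def main_counts(g):
        X, Z = g["X"], g["Z"]
        a_counts = np.stack([
            np.nansum(X == 1.0, axis=0),
            np.nansum(X == 0.0, axis=0),
            np.nansum(X == -1.0, axis=0),
        ], axis=1).astype(float)
        d_counts = np.stack([
            np.nansum(Z == 1.0, axis=0),
            np.nansum(Z == 0.0, axis=0),
        ], axis=1).astype(float)
        return a_counts, d_counts

    a_hi, d_hi = main_counts(g_hi)
    a_lo, d_lo = main_counts(g_lo)
    for kind, ch, cl in (("a", a_hi, a_lo), ("d", d_hi, d_lo)):
        chi2, df, p, unt = _pearson_from_counts(ch, cl)
        frames.append(pd.DataFrame({
            "kind": kind, "locus1": np.arange(m), "locus2": -1,
            "chi2": chi2, "df": df, "p": p, "untestable": unt,
        }))

    # interaction effects: level counts from indicator cross-products
    def pair_counts(g):
        P, N, H, V = g["P"], g["N"], g["H"], g["V"]
        VV = V.T @ V
        out = {}
        c1 = P.T @ P + N.T @ N
        cm1 = P.T @ N + N.T @ P
        out["aa"] = (c1, VV - c1 - cm1, cm1)
        a1 = P.T @ H
        am1 = N.T @ H
        out["ad"] = (a1, VV - a1 - am1, am1)
        d1 = H.T @ P
        dm1 = H.T @ N
        out["da"] = (d1, VV - d1 - dm1, dm1)
        e1 = H.T @ H
        out["dd"] = (e1, VV - e1, None)
        return out

    pc_hi = pair_counts(g_hi)
    pc_lo = pair_counts(g_lo)
    for kind in INTERACTION_KINDS:
        levels_hi = [mat[iu_j, iu_k] for mat in pc_hi[kind] if mat is not None]
        levels_lo = [mat[iu_j, iu_k] for mat in pc_lo[kind] if mat is not None]
        chi2, df, p, unt = _pearson_from_counts(
            np.stack(levels_hi, axis=1), np.stack(levels_lo, axis=1))
        frames.append(pd.DataFrame({
            "kind": kind, "locus1": iu_j, "locus2": iu_k,
            "chi2": chi2, "df": df, "p": p, "untestable": unt,
        }))

    table = pd.concat(frames, ignore_index=True)
    table["is_main"] = table["kind"].isin(("a", "d"))
    order = np.empty(len(table), dtype=np.int64)
    # canonical enumeration order without building descriptor objects
    main_mask = table["is_main"].to_numpy()
    j = table["locus1"].to_numpy()
    k = table["locus2"].to_numpy()
    kind_idx_main = (table["kind"] == "d").to_numpy().astype(np.int64)
    order[main_mask] = 2 * j[main_mask] + kind_idx_main[main_mask]
    inter = ~main_mask
    kind_idx_int = table.loc[inter, "kind"].map(
        {kd: i for i, kd in enumerate(INTERACTION_KINDS)}).to_numpy()
    pair_rank = j[inter] * m - j[inter] * (j[inter] + 1) // 2 + (k[inter] - j[inter] - 1)
    order[inter] = 2 * m + 4 * pair_rank + kind_idx_int
    table["order"] = order
    return table.sort_values("order").reset_index(drop=True)


def _descriptor_from_row(row) -> EffectDescriptor:
    locus2 = None if row.locus2 < 0 else int(row.locus2)
    return EffectDescriptor(row.kind, int(row.locus1), locus2)


def screen_top_effects(
    encoding: EffectEncoding,
    phenotypes: pd.Series,
    already_selected=(),
    cap: int = 100,
    alpha: float = 0.05,
    fraction: float = 0.10,
) -> list[ScreenResult]:
    """Rank candidate effects by extreme-group chi-square and keep the best.

    Up to ``cap`` main effects and ``cap`` interaction effects with the
    smallest p-values are returned (p <= alpha, untestable effects and
    ``already_selected`` descriptors excluded), main effects first, each
    category ascending by p with ties broken by canonical effect order.
    """
    if cap < 1:
        raise ScreeningError("cap must be >= 1")
    high, low = select_extremes(phenotypes, fraction)
    table = screen_all_effects(encoding, high, low)
    m = encoding.m
    excluded = {descriptor_order_index(d, m) for d in already_selected}
    if excluded:
        table = table[~table["order"].isin(excluded)]
    table = table[~table["untestable"] & (table["p"] <= alpha)]
    out: list[ScreenResult] = []
    for is_main in (True, False):
        cat = table[table["is_main"] == is_main]
        cat = cat.sort_values(["p", "order"], kind="mergesort").head(cap)
        for row in cat.itertuples():
            out.append(ScreenResult(_descriptor_from_row(row), float(row.chi2),
                                    int(row.df), float(row.p)))
    return out


def screening_report(results: list[ScreenResult], markers) -> pd.DataFrame:
    """TSV-ready screening report: effect,kind,locus1,locus2,chi2,df,p."""
    rows = []
    for r in results:
        d = r.descriptor
        rows.append({
            "effect": d.name(markers),
            "kind": d.kind,
            "locus1": markers[d.locus1],
            "locus2": markers[d.locus2] if d.locus2 is not None else "",
            "chi2": r.chi2,
            "df": r.df,
            "p": r.p,
        })
    return pd.DataFrame(rows, columns=["effect", "kind", "locus1", "locus2", "chi2", "df", "p"])
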