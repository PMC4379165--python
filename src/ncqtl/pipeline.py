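"""Iterative genome scan: screen, shrink, test, correct, repeat, joint fit.

The scan alternates between (1) extreme-group chi-square screening of all
candidate effects on the current working phenotype, (2) an empirical-Bayes
shrinkage fit of the screened effects, (3) LOD testing of the non-zero
effects, and (4) subtracting the newly significant effects from the
phenotype (y' = y - W b) so later passes can uncover effects masked by
the strong ones.  The loop stops when a pass adds no significant effect.
Finally every accumulated effect is refitted jointly on the ORIGINAL
phenotype, LOD-filtered once more, and reported with its screening
statistics, effect estimate and the percentage of phenotypic variance it
explains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .ebayes import EBayesConfig, EBayesFit, fit_empirical_bayes
from .model_matrix import EffectDescriptor, EffectEncoding, descriptor_order_index
from .population import NCIIPopulation, allele_frequencies
from .screening import ScreenResult, screen_top_effects
from .significance import lod_for_effect

logger = logging.getLogger(__name__)


@dataclass
class ScanConfig:
    """Tuning parameters of the iterative scan (defaults follow the method)."""

    extreme_fraction: float = 0.10
    cap: int = 100
    alpha: float = 0.05
    lod_threshold: float = 2.0
    max_outer_iter: int = 20
    ebayes: EBayesConfig = field(default_factory=EBayesConfig)

    def __post_init__(self) -> None:
        if not 0 < self.extreme_fraction <= 0.5:
            raise ValueError("extreme_fraction must be in (0, 0.5]")
        if self.cap < 1 or self.max_outer_iter < 1:
            raise ValueError("cap and max_outer_iter must be >= 1")
        if self.lod_threshold <= 0 or not 0 < self.alpha <= 1:
            raise ValueError("thresholds out of range")


@dataclass(frozen=True)
class QTLRecord:
    """One reported QTL effect (columns mirror the method's report layout)."""

    descriptor: EffectDescriptor
    markers: tuple[str, ...]
    allele_freqs: tuple[float, ...]
    chi2: float
    df: int
    p: float
    lod: float
    effect: float
    r2: float


def correct_phenotype(y: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Phenotype corrected for known effects: y' = y - W b."""
    y = np.asarray(y, dtype=float)
    if W is None or np.size(b) == 0:
        return y.copy()
    return y - np.asarray(W, dtype=float) @ np.asarray(b, dtype=float)


def variance_explained(w: np.ndarray, gamma: float, y: np.ndarray) -> float:
    """Percent of total phenotypic variance explained by one effect.

    100 * Var(w * gamma) / Var(y), population variance (divisor n).
    """
    y = np.asarray(y, dtype=float)
    var_y = float(y.var())
    if var_y <= 0:
        raise ValueError("phenotype has zero variance")
    return 100.0 * float((np.asarray(w, dtype=float) * gamma).var()) / var_y


class QTLScan(BaseEstimator):
    """Estimator-style interface to the iterative scan.

    ``fit(population)`` runs the scan on the phenotyped individuals and
    exposes the results as fitted attributes:

    qtl_ : list[QTLRecord]        -- the final report.
    intercept_ : float            -- mu-hat of the final joint fit.
    sigma2_ : float               -- residual variance of the final joint fit.
    final_fit_ : EBayesFit        -- converged joint model (reported effects).
    n_outer_iter_ : int
    """

    def __init__(self, extreme_fraction: float = 0.10, cap: int = 100,
                 alpha: float = 0.05, lod_threshold: float = 2.0,
                 max_outer_iter: int = 20, ebayes: EBayesConfig | None = None):
        self.extreme_fraction = extreme_fraction
        self.cap = cap
        self.alpha = alpha
        self.lod_threshold = lod_threshold
        self.max_outer_iter = max_outer_iter
        self.ebayes = ebayes

    def fit(self, population: NCIIPopulation):
        config = ScanConfig(self.extreme_fraction, self.cap, self.alpha,
                            self.lod_threshold, self.max_outer_iter,
                            self.ebayes or EBayesConfig())
        ids = population.mapped_ids()
        if len(ids) < 2:
            raise ValueError("need at least 2 phenotyped individuals")
        y0 = population.phenotypes.loc[ids].to_numpy(dtype=float)
        if y0.var() <= 0:
            raise ValueError("phenotype has zero variance")
        encoding = EffectEncoding.from_population(population, ids=ids)
        markers = encoding.markers
        m = encoding.m

        y = y0.copy()
        accumulated: dict[EffectDescriptor, ScreenResult] = {}
        for outer in range(1, config.max_outer_iter + 1):
            results = screen_top_effects(
                encoding, pd.Series(y, index=ids), already_selected=accumulated,
                cap=config.cap, alpha=config.alpha,
                fraction=config.extreme_fraction)
            if not results:
                logger.info("scan pass %d: no candidate effects survive screening", outer)
                break
            descs = [r.descriptor for r in results]
            Z = encoding.columns(descs)
            fit = fit_empirical_bayes(y, Z, config.ebayes)
            newly: list[int] = []
            for k in np.flatnonzero(fit.nonzero):
                test = lod_for_effect(fit, int(k), y, Z, descs[k])
                if test.lod >= config.lod_threshold:
                    newly.append(int(k))
            logger.info(
                "scan pass %d: screened=%d selected=%d significant=%d cumulative=%d",
                outer, 2 * m + 2 * m * (m - 1), len(results), len(newly),
                len(accumulated) + len(newly))
            if not newly:
                break
            for k in newly:
                accumulated[descs[k]] = results[k]
            y = correct_phenotype(y, Z[:, newly], fit.gamma[newly])
        self.n_outer_iter_ = outer

        # final joint fit of every accumulated effect on the original phenotype
        records: list[QTLRecord] = []
        if accumulated:
            freq = allele_frequencies(population, ids=ids)
            descs = sorted(accumulated, key=lambda d: (not d.is_main,
                                                       accumulated[d].p,
                                                       descriptor_order_index(d, m)))
            Z = encoding.columns(descs)
            final = fit_empirical_bayes(y0, Z, config.ebayes)
            for k, desc in enumerate(descs):
                if not final.nonzero[k]:
                    continue
                test = lod_for_effect(final, k, y0, Z, desc)
                if test.lod < config.lod_threshold:
                    continue
                screen = accumulated[desc]
                names = tuple(markers[j] for j in desc.loci())
                freqs = tuple(round(float(freq[name]), 6) for name in names)
                records.append(QTLRecord(
                    descriptor=desc, markers=names, allele_freqs=freqs,
                    chi2=screen.chi2, df=screen.df, p=screen.p,
                    lod=test.lod, effect=float(final.gamma[k]),
                    r2=variance_explained(Z[:, k], float(final.gamma[k]), y0)))
            self.final_fit_ = final
            self.intercept_ = final.beta
            self.sigma2_ = final.sigma2
        else:
            self.final_fit_ = None
            self.intercept_ = float(y0.mean())
            self.sigma2_ = float(y0.var())
        # report order: main effects first, then interactions, each ascending p
        records.sort(key=lambda r: (not r.descriptor.is_main, r.p,
                                    descriptor_order_index(r.descriptor, m)))
        self.qtl_ = records
        return self


def run_scan(population: NCIIPopulation, config: ScanConfig | None = None
             ) -> list[QTLRecord]:
    """Run the full iterative scan; thin wrapper over :class:`QTLScan`."""
    config = config or ScanConfig()
    scan = QTLScan(config.extreme_fraction, config.cap, config.alpha,
                   config.lod_threshold, config.max_outer_iter, config.ebayes)
    return scan.fit(population).qtl_


def qtl_report(records: list[QTLRecord]) -> pd.DataFrame:
    """Tabular QTL report (one row per effect, report-ready columns)."""
    rows = []
    for i, r in enumerate(records, start=1):
        rows.append({
            "qtl": i,
            "type": r.descriptor.kind,
            "position": "×".join(r.markers),
            "freq_locus1": r.allele_freqs[0],
            "freq_locus2": r.allele_freqs[1] if len(r.allele_freqs) > 1 else "",
            "chi2": r.chi2,
            "p": r.p,
            "lod": r.lod,
            "effect": r.effect,
            "r2_percent": r.r2,
        })
    return pd.DataFrame(rows, columns=["qtl", "type", "position", "freq_locus1",
                                       "freq_locus2", "chi2", "p", "lod",
                                       "effect", "r2_percent"])
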