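import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ncqtl import NCIIPopulation

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_population(parent_a_codes, parent_b_codes, markers=None,
                    phenotypes=None, n_f1_per_b=2, seed=0):
    """Small partial-NCII population built from explicit parent genotypes.

    ``parent_a_codes`` / ``parent_b_codes``: 2-D arrays of inbred codes
    (0/2).  A partial pedigree is drawn with ``n_f1_per_b`` crosses per
    group-B parent and F1 genotypes are deduced as the parental mean.
    """
    parent_a_codes = np.asarray(parent_a_codes, dtype=float)
    parent_b_codes = np.asarray(parent_b_codes, dtype=float)
    n_a, m = parent_a_codes.shape
    n_b = parent_b_codes.shape[0]
    markers = markers or [f"M{j + 1:03d}" for j in range(m)]
    a_ids = [f"A{i + 1:03d}" for i in range(n_a)]
    b_ids = [f"B{i + 1:03d}" for i in range(n_b)]
    rng = np.random.default_rng(seed)
    rows, ids, roles, pedigree = [], [], [], []
    for i, codes in enumerate(parent_a_codes):
        rows.append(codes); ids.append(a_ids[i]); roles.append("parentA")
    for i, codes in enumerate(parent_b_codes):
        rows.append(codes); ids.append(b_ids[i]); roles.append("parentB")
    count = 0
    for i in range(n_b):
        mates = rng.choice(n_a, size=min(n_f1_per_b, n_a), replace=False)
        for a_idx in mates:
            count += 1
            f1 = f"H{count:03d}"
            rows.append((parent_a_codes[a_idx] + parent_b_codes[i]) / 2.0)
            ids.append(f1); roles.append("F1")
            pedigree.append({"f1_id": f1, "parent_a": a_ids[a_idx],
                             "parent_b": b_ids[i]})
    genotypes = pd.DataFrame(rows, index=pd.Index(ids, name="id"), columns=markers)
    pheno = None
    if phenotypes is not None:
        pheno = pd.Series(phenotypes, index=genotypes.index)
    return NCIIPopulation(
        genotypes=genotypes,
        roles=pd.Series(roles, index=genotypes.index),
        pedigree=pd.DataFrame(pedigree, columns=["f1_id", "parent_a", "parent_b"]),
        phenotypes=pheno,
    )


@pytest.fixture
def toy_population():
    """2 group-A parents, 1 group-B parent, 2 F1, 3 markers."""
    return make_population(
        parent_a_codes=[[2, 0, 2], [0, 0, 2]],
        parent_b_codes=[[0, 2, 2]],
        markers=["mk1", "mk2", "mk3"],
        phenotypes=[1.0, 2.0, 3.0, 1.5, 2.5],
    )


@pytest.fixture
def random_population():
    """Mid-size random population with some missing genotypes."""
    rng = np.random.default_rng(7)
    pa = 2.0 * (rng.random((30, 12)) < 0.5)
    pb = 2.0 * (rng.random((15, 12)) < 0.5)
    pop = make_population(pa, pb, seed=3)
    # knock out a few parent genotypes (missing codes)
    geno = pop.genotypes.copy()
    holes = rng.choice(geno.size, size=10, replace=False)
    flat = geno.to_numpy()
    flat.flat[holes] = np.nan
    geno.iloc[:, :] = flat
    rng2 = np.random.default_rng(11)
    pheno = pd.Series(rng2.normal(size=len(geno)), index=geno.index)
    return NCIIPopulation(genotypes=geno, roles=pop.roles, pedigree=pop.pedigree,
                          phenotypes=pheno, non_inbred_parent="ignore")
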