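import numpy as np
import pandas as pd
import pytest
from scipy import stats

from prcgwas import SimConfig, make_fixture_cohort, simulate_genotypes


@pytest.fixture
def rng():
    return np.random.default_rng(20231207)


@pytest.fixture(scope="session")
def qc_mixed_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("qc_mixed")
    truth = make_fixture_cohort("qc_mixed", 7, d)
    return d, truth


@pytest.fixture(scope="session")
def qc_mixed_tables(qc_mixed_dir):
    d, truth = qc_mixed_dir
    pcs = pd.read_csv(d / "pcs.tsv", sep="\t", index_col="individual_id")
    cov = pd.read_csv(d / "covariates.tsv", sep="\t",
                      index_col="individual_id")
    related = [ln.strip() for ln in
               (d / "related_exclude.txt").read_text().splitlines()
               if ln.strip()]
    return pcs, cov, related, truth


@pytest.fixture(scope="session")
def small_genotypes():
    return simulate_genotypes(SimConfig(n_individuals=400, n_snps=40,
                                        seed=11))


def ols_oracle(y, X):
    """Textbook normal-equations OLS: beta, SE, two-sided t p-values.

    Independent of the package's fitting path (explicit inverse instead of
    least-squares solve).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    sigma2 = resid @ resid / (n - k)
    se = np.sqrt(np.diag(XtX_inv) * sigma2)
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), n - k)
    return beta, se, p


def bh_reference(pvals, alpha):
    """Step-up Benjamini-Hochberg oracle: reject flags and adjusted q."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = ranked * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    crit = ranked <= alpha * np.arange(1, m + 1) / m
    k = np.max(np.nonzero(crit)[0]) + 1 if crit.any() else 0
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    q_full = np.empty(m)
    q_full[order] = np.minimum(q, 1.0)
    return reject, q_full


def collapse_brute_force(genos):
    """Per-individual burden code by direct case analysis over variants."""
    out = []
    for row in genos:
        if any(g >= 2 for g in row):
            out.append(2)
        elif any(g == 1 for g in row):
            out.append(1)
        else:
            out.append(0)
    return out
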