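"""Global methylation profiling and gene-set overrepresentation.

Covers sample-level views of the methylome (PCA over 2-kb window means,
feature-class methylation distributions, the CIMP marker check) and a
local hypergeometric overrepresentation test against GMT gene-set
collections.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .annotation import cimp_panel
from .diffmeth import bh_adjust, mwu_test
from .io import MethylationMatrix

logger = logging.getLogger(__name__)


def global_windows_pca(matrix: MethylationMatrix, n_components: int = 2):
    """PCA of samples on genome-wide window mean methylation.

    Windows with any missing sample are dropped listwise; values are
    centered per window (no scaling -- methylation is already on a common
    [0, 1] scale).  Returns (scores DataFrame samples x PCs, explained
    variance fractions).
    """
    if len(matrix.samples) < 3:
        raise ValueError("need >= 3 samples")
    V = matrix.values.to_numpy(dtype=float)
    complete = ~np.isnan(V).any(axis=1)
    if complete.sum() < 3:
        raise ValueError("fewer than 3 complete windows")
    X = V[complete].T  # samples x windows
    n_components = min(n_components, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X - X.mean(axis=0))
    cols = [f"PC{i+1}" for i in range(scores.shape[1])]
    return (
        pd.DataFrame(scores, index=matrix.samples, columns=cols),
        pca.explained_variance_ratio_,
    )


def feature_distribution(samples: dict, track: pd.DataFrame) -> pd.DataFrame:
    """Per-sample methylation distribution over a feature track.

    For each sample, region means over the track are computed and
    summarised by (min, Q1, median, Q3, max, mean, n_regions).  Invariant
    to the order of intervals.
    """
    from .io import map_to_regions

    mat = map_to_regions(samples, track)
    rows = []
    for sid in mat.samples:
        v = mat.values[sid].dropna().to_numpy()
        if len(v) == 0:
            rows.append((sid, *([np.nan] * 6), 0))
            continue
        q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
        rows.append((sid, v.min(), q1, med, q3, v.max(), v.mean(), len(v)))
    return pd.DataFrame(
        rows, columns=["sample", "min", "q1", "median", "q3", "max", "mean", "n_regions"]
    ).set_index("sample")


def cimp_check(
    promoter_matrix: MethylationMatrix, group_a: str, group_b: str, alpha: float = 0.05
) -> tuple[pd.DataFrame, bool]:
    """Methylation of the six CIMP marker-gene promoters between groups.

    The promoter matrix must be indexed by gene name and contain all six
    panel genes (a missing marker raises, naming the gene).  P-values are
    BH-adjusted across the six-marker panel; the returned flag is True iff
    no marker reaches adjusted p < alpha -- the no-CIMP-difference outcome.
    """
    rows = []
    for gene in cimp_panel():
        if gene not in promoter_matrix.values.index:
            raise ValueError(f"CIMP marker promoter missing from matrix: {gene}")
        va = promoter_matrix.values.loc[gene, promoter_matrix.samples_of(group_a)]
        vb = promoter_matrix.values.loc[gene, promoter_matrix.samples_of(group_b)]
        _, p = mwu_test(va.to_numpy(dtype=float), vb.to_numpy(dtype=float))
        rows.append((gene, float(np.nanmean(va)), float(np.nanmean(vb)), p))
    table = pd.DataFrame(rows, columns=["gene", f"mean_{group_a}", f"mean_{group_b}", "p_mwu"])
    table["p_adj"] = bh_adjust(table["p_mwu"].to_numpy())
    concordant = bool((table["p_adj"] >= alpha).all())
    return table, concordant


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>genes...``."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict, path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def ora_test(query_genes, gene_set, universe) -> tuple[int, float, float]:
    """One-sided hypergeometric overrepresentation test.

    Query and set are intersected with the universe first (dropped members
    logged).  With universe size M, set size K, query size n and overlap k,
    p = P(X >= k) for X ~ Hypergeom(M, K, n).  Returns (overlap,
    odds_ratio, p).
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q = set(query_genes)
    dropped = len(q - uni)
    if dropped:
        logger.info("ora_test: %d query genes outside the universe dropped", dropped)
    q &= uni
    s = set(gene_set) & uni
    M, K, n = len(uni), len(s), len(q)
    k = len(q & s)
    p = float(stats.hypergeom.sf(k - 1, M, K, n))
    a, b_, c, d = k, K - k, n - k, M - K - n + k
    odds = (a * d) / (b_ * c) if b_ * c > 0 else np.inf
    return k, float(odds), min(p, 1.0)


def ora_collection(query_genes, collection: dict, universe) -> pd.DataFrame:
    """Run :func:`ora_test` over a named collection and BH-adjust per
    collection.  Sets with no member in the universe are dropped with a
    warning."""
    rows = []
    for name, members in collection.items():
        s = set(members) & set(universe)
        if not s:
            logger.warning("gene set %r has no member in the universe; dropped", name)
            continue
        k, odds, p = ora_test(query_genes, members, universe)
        rows.append((name, k, len(s), odds, p))
    df = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "odds_ratio", "p"])
    if not df.empty:
        df["p_adj"] = bh_adjust(df["p"].to_numpy())
    else:
        df["p_adj"] = []
    return df.sort_values("p", kind="mergesort").reset_index(drop=True)


def smooth_profile(positions, values, frac: float = 0.2) -> np.ndarray:
    """LOESS-style smoother for canyon methylation profiles (plot helper)."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    sm = lowess(values, positions, frac=frac, return_sorted=False)
    return np.asarray(sm)
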