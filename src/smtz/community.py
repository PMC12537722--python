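"""Community composition analysis on ASV count tables.

Implements the dissimilarity chain applied to 16S rRNA gene amplicon data:
taxonomic aggregation of ASV counts, relative abundance with a pooled
"Other_Families" tail, Bray-Curtis dissimilarity, classical principal
coordinates analysis (Gower-centered metric scaling), and a multi-factor
PERMANOVA with sequential (Type-I) sums of squares computed from hat-matrix
traces on the Gower-centered inner-product matrix, significance by free
permutation of sample rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TAXONOMIC_RANKS",
    "CountTable",
    "DistanceMatrix",
    "PCoAResult",
    "PermanovaResult",
    "aggregate_to_rank",
    "relative_abundance",
    "bray_curtis",
    "pcoa",
    "permanova",
]

TAXONOMIC_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


@dataclass
class CountTable:
    """Samples x ASVs count matrix with taxonomy and sample metadata.

    taxonomy maps each ASV id to a semicolon-delimited lineage
    (domain;phylum;class;order;family[;genus[;species]]); metadata is a
    DataFrame indexed by sample id carrying at least bay, season, depth, site.
    """

    sample_ids: list[str]
    asv_ids: list[str]
    counts: np.ndarray
    taxonomy: dict[str, str]
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sample_ids), len(self.asv_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.asv_ids)} ASVs"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        missing_tax = [a for a in self.asv_ids if a not in self.taxonomy]
        if missing_tax:
            raise ValueError(f"taxonomy missing for ASVs: {missing_tax[:5]}")
        missing_meta = [s for s in self.sample_ids if s not in self.metadata.index]
        if missing_meta:
            raise ValueError(f"metadata missing for samples: {missing_meta[:5]}")

    def totals(self) -> np.ndarray:
        """Total count per sample (library size)."""
        return self.counts.sum(axis=1)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with a zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-10):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < -1e-12):
            raise ValueError("distances must be non-negative")


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # samples x retained axes (PC1, PC2, ...)
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray  # per retained axis, of the positive-eigenvalue sum


@dataclass
class PermanovaResult:
    """Sequential PERMANOVA table for a factorial design on a distance matrix."""

    terms: pd.DataFrame  # name, df, sum_of_squares, pseudo_F, r_squared, p_value
    ss_residual: float
    ss_total: float
    df_residual: int
    n_permutations: int
    seed: int | None = None

    def to_dataframe(self) -> pd.DataFrame:
        table = self.terms.copy()
        extra = pd.DataFrame(
            [
                {
                    "name": "Residual",
                    "df": self.df_residual,
                    "sum_of_squares": self.ss_residual,
                    "pseudo_F": np.nan,
                    "r_squared": self.ss_residual / self.ss_total,
                    "p_value": np.nan,
                },
                {
                    "name": "Total",
                    "df": self.df_residual + int(self.terms["df"].sum()),
                    "sum_of_squares": self.ss_total,
                    "pseudo_F": np.nan,
                    "r_squared": 1.0,
                    "p_value": np.nan,
                },
            ]
        )
        return pd.concat([table, extra], ignore_index=True)


def _rank_index(rank: str) -> int:
    try:
        return TAXONOMIC_RANKS.index(rank.lower())
    except ValueError:
        raise ValueError(
            f"unknown taxonomic rank {rank!r}; expected one of {TAXONOMIC_RANKS}"
        ) from None


def aggregate_to_rank(table: CountTable, rank: str) -> CountTable:
    """Sum ASV counts over shared labels at a taxonomic rank.

    ASVs whose lineage does not reach the rank are pooled under "Unassigned".
    Total counts per sample are conserved.
    """
    level = _rank_index(rank)
    labels = []
    lineages = []
    for asv in table.asv_ids:
        parts = [p.strip() for p in table.taxonomy[asv].split(";")]
        if level < len(parts) and parts[level]:
            labels.append(parts[level])
            lineages.append(";".join(parts[: level + 1]))
        else:
            labels.append("Unassigned")
            lineages.append("Unassigned")
    unique = sorted(set(labels))
    index = {lab: i for i, lab in enumerate(unique)}
    agg = np.zeros((len(table.sample_ids), len(unique)), dtype=table.counts.dtype)
    new_tax = {}
    for j, (lab, lineage) in enumerate(zip(labels, lineages)):
        agg[:, index[lab]] += table.counts[:, j]
        new_tax[lab] = lineage
    return CountTable(
        sample_ids=list(table.sample_ids),
        asv_ids=unique,
        counts=agg,
        taxonomy=new_tax,
        metadata=table.metadata,
    )


def relative_abundance(
    table: CountTable, top_k: int | None = 15, other_label: str = "Other_Families"
) -> pd.DataFrame:
    """Per-sample proportions, pooling taxa beyond the top_k into one column.

    top_k taxa are chosen by mean relative abundance across samples (ties
    broken lexicographically); rows sum to 1.  top_k=None keeps every taxon.
    """
    totals = table.totals().astype(float)
    zero = [s for s, t in zip(table.sample_ids, totals) if t == 0]
    if zero:
        raise ValueError(f"samples with zero total count: {zero}")
    props = table.counts / totals[:, None]
    frame = pd.DataFrame(props, index=table.sample_ids, columns=table.asv_ids)
    if top_k is None or top_k >= frame.shape[1]:
        return frame
    order = sorted(frame.columns, key=lambda c: (-frame[c].mean(), c))
    keep = order[:top_k]
    rest = [c for c in frame.columns if c not in keep]
    out = frame[keep].copy()
    out[other_label] = frame[rest].sum(axis=1)
    return out


def bray_curtis(table: CountTable, use_relative: bool = True) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity, d(x, y) = sum|x-y| / sum(x+y).

    Computed on relative abundances by default since library sizes differ;
    use_relative=False operates on raw counts.
    """
    if len(table.sample_ids) < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    x = table.counts.astype(float)
    if use_relative:
        totals = x.sum(axis=1)
        zero = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        if zero:
            raise ValueError(f"samples with zero total count: {zero}")
        x = x / totals[:, None]
    diff = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    summ = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    if np.any((summ == 0) & ~np.eye(len(x), dtype=bool)):
        raise ValueError("Bray-Curtis undefined for a pair of all-zero samples")
    with np.errstate(invalid="ignore"):
        d = np.where(summ > 0, diff / np.where(summ == 0, 1.0, summ), 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(sample_ids=list(table.sample_ids), values=d)


def _gower_center(d_squared: np.ndarray) -> np.ndarray:
    n = d_squared.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d_squared @ j


def pcoa(d: DistanceMatrix, eps: float = 1e-12) -> PCoAResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Gower-centers -0.5 * D^2, eigendecomposes, and scales eigenvectors by the
    square roots of the positive eigenvalues.  Negative eigenvalues (possible
    for semi-metric dissimilarities like Bray-Curtis) are reported in
    ``eigenvalues`` but excluded from the coordinates; no Lingoes/Cailliez
    correction is applied.  Proportions explained are relative to the sum of
    positive eigenvalues.
    """
    n = len(d.sample_ids)
    if n < 2:
        raise ValueError("PCoA needs at least 2 samples")
    g = _gower_center(d.values**2)
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    # deterministic sign: largest-magnitude loading of each axis positive
    for k in range(eigvecs.shape[1]):
        i = int(np.argmax(np.abs(eigvecs[:, k])))
        if eigvecs[i, k] < 0:
            eigvecs[:, k] = -eigvecs[:, k]
    tol = eps * max(abs(eigvals[0]), 1.0)
    positive = eigvals > tol
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    pos_sum = eigvals[positive].sum()
    proportion = eigvals[positive] / pos_sum if pos_sum > 0 else eigvals[positive]
    columns = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=d.sample_ids, columns=columns),
        eigenvalues=eigvals,
        proportion_explained=proportion,
    )


def _term_matrix(metadata: pd.DataFrame, term: str) -> np.ndarray:
    """Design columns for one model term; 'a:b' is the interaction product."""
    blocks = []
    for name in term.split(":"):
        if name not in metadata.columns:
            raise ValueError(f"term {term!r}: column {name!r} not in metadata")
        col = metadata[name]
        if pd.api.types.is_numeric_dtype(col):
            blocks.append(col.to_numpy(dtype=float)[:, None])
        else:
            dummies = pd.get_dummies(col.astype(str), drop_first=True)
            dummies = dummies[sorted(dummies.columns)]
            blocks.append(dummies.to_numpy(dtype=float))
    out = blocks[0]
    for nxt in blocks[1:]:
        out = (out[:, :, None] * nxt[:, None, :]).reshape(len(nxt), -1)
    return out


def _orthonormal_basis(x: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Orthonormal basis of the column space of x (rank-revealing SVD)."""
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    rank = int(np.sum(s > tol * (s[0] if s.size else 1.0)))
    return u[:, :rank]


def permanova(
    d: DistanceMatrix,
    metadata: pd.DataFrame,
    terms: list[str],
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """Permutational multivariate analysis of variance on a distance matrix.

    Partitions the total sum of squares tr(G), where G is the Gower-centered
    -0.5 * D^2 matrix, over the model terms added sequentially (Type-I):
    SS(term_j) = tr(H_j G) - tr(H_{j-1} G) with H_j the hat matrix of the
    design including intercept and terms 1..j.  pseudo-F per term uses the
    final residual mean square; p-values come from free permutation of sample
    rows, p = (#{F* >= F} + 1) / (n_permutations + 1).

    metadata rows are aligned to ``d.sample_ids``; terms use column names,
    with 'a:b' denoting an interaction.  Categorical columns get treatment
    dummies, numeric columns enter linearly.
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be at least 99")
    missing = [s for s in d.sample_ids if s not in metadata.index]
    if missing:
        raise ValueError(f"metadata missing for samples: {missing[:5]}")
    meta = metadata.loc[d.sample_ids]
    n = len(d.sample_ids)

    g = _gower_center(d.values**2)
    ss_total = float(np.trace(g))

    # cumulative orthonormal bases; hat-matrix traces follow as tr(Q Q^T G)
    design = np.ones((n, 1))
    bases: list[np.ndarray] = []
    dfs: list[int] = []
    prev_rank = 1
    for term in terms:
        design = np.hstack([design, _term_matrix(meta, term)])
        q = _orthonormal_basis(design)
        df_term = q.shape[1] - prev_rank
        if df_term == 0:
            raise ValueError(
                f"rank-deficient design: term {term!r} is aliased with earlier terms"
            )
        prev_rank = q.shape[1]
        bases.append(q)
        dfs.append(df_term)

    df_model = prev_rank - 1
    df_residual = n - prev_rank
    if df_residual <= 0:
        raise ValueError("no residual degrees of freedom for this design")

    def _explained(gmat: np.ndarray) -> np.ndarray:
        """Cumulative model SS tr(H_j G) for each term j (intercept removed
        implicitly: G is double-centered so the intercept contributes 0)."""
        return np.array([np.einsum("ij,ij->", q, gmat @ q) for q in bases])

    cum = _explained(g)
    ss_terms = np.diff(np.concatenate([[0.0], cum]))
    ss_residual = ss_total - cum[-1]
    ms_residual = ss_residual / df_residual
    f_obs = (ss_terms / np.array(dfs)) / ms_residual

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms), dtype=int)
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        cum_p = _explained(gp)
        ss_p = np.diff(np.concatenate([[0.0], cum_p]))
        res_p = ss_total - cum_p[-1]
        f_p = (ss_p / np.array(dfs)) / (res_p / df_residual)
        exceed += f_p >= f_obs - 1e-12
    p_values = (exceed + 1) / (n_permutations + 1)

    table = pd.DataFrame(
        {
            "name": terms,
            "df": dfs,
            "sum_of_squares": ss_terms,
            "pseudo_F": f_obs,
            "r_squared": ss_terms / ss_total,
            "p_value": p_values,
        }
    )
    return PermanovaResult(
        terms=table,
        ss_residual=float(ss_residual),
        ss_total=ss_total,
        df_residual=int(df_residual),
        n_permutations=n_permutations,
        seed=seed,
    )
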