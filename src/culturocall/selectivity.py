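"""Media selectivity: family-level enrichment ranking and community divergence.

Which growth conditions select for which taxa? Two complementary views:

* a family × condition matrix of relative abundances (how much of each
  culture a family occupies), from which the top conditions per family are
  ranked — the dot-plot view;
* per-condition Bray-Curtis divergence of each cultured community from its
  own experiment's inoculum, with classical PCoA for ordination — the
  most-divergent (most selective) conditions rise to the top.

Divergence is always computed against the same-experiment inoculum:
inocula differ between donor birds, so cross-experiment comparison would
conflate inoculum and medium effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io import RANKS, ValidationError

__all__ = [
    "family_of",
    "family_abundance",
    "rank_conditions",
    "bray_curtis",
    "PCoAResult",
    "pcoa",
    "condition_divergence",
]


def family_of(taxonomy: pd.DataFrame, otu_id: str) -> str:
    """Family bin for an OTU: the annotated family, or an ``unassigned_*``
    bin labelled by the deepest annotated taxon when family is absent."""
    if otu_id not in taxonomy.index:
        return "unassigned"
    row = taxonomy.loc[otu_id]
    fam = row.get("family")
    if pd.notna(fam):
        return str(fam)
    deepest_name = None
    for rank in RANKS[: RANKS.index("family")]:
        if pd.notna(row.get(rank)):
            deepest_name = str(row[rank])
    return f"unassigned_{deepest_name}" if deepest_name else "unassigned"


def family_abundance(
    ra: pd.DataFrame, taxonomy: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Family × condition matrix of summed member relative abundances.

    Restricted to culture samples; columns are condition labels, which must
    be unique across culture samples.
    """
    cultures = [s for s in metadata.index[metadata["role"] == "culture"] if s in ra.columns]
    if not cultures:
        raise ValidationError("no culture samples present in the table")
    conditions = metadata.loc[cultures, "condition"]
    dup = conditions[conditions.duplicated()]
    if len(dup):
        raise ValidationError(
            f"condition label(s) shared by multiple culture samples: {sorted(set(dup))}"
        )
    families = pd.Series({o: family_of(taxonomy, o) for o in ra.index})
    mat = ra[cultures].groupby(families).sum()
    mat.columns = [conditions[s] for s in cultures]
    mat = mat[sorted(mat.columns)]
    mat.index.name = "family"
    return mat


def rank_conditions(matrix: pd.DataFrame, family: str, k: int) -> pd.DataFrame:
    """Top-k conditions for a family, by descending abundance.

    Ties are broken lexicographically by condition label; if k exceeds the
    number of conditions, all conditions are returned.
    """
    if family not in matrix.index:
        raise KeyError(
            f"family {family!r} not in matrix; available: {sorted(matrix.index)}"
        )
    row = matrix.loc[family]
    order = sorted(row.index, key=lambda c: (-row[c], c))[: max(k, 0)]
    return pd.DataFrame({"condition": order, "abundance": row[order].to_numpy()})


def bray_curtis(ra: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis distances between sample columns.

    On proportion columns (each summing to 1) this equals
    ``1 - sum_k min(p_ki, p_kj)``.
    """
    cols = ra.columns
    dist = squareform(pdist(ra.to_numpy().T, metric="braycurtis"))
    return pd.DataFrame(dist, index=cols, columns=cols)


@dataclass
class PCoAResult:
    """Classical-scaling ordination of a distance matrix.

    ``coordinates`` holds one row per sample, axes ordered by descending
    eigenvalue and scaled by sqrt(eigenvalue). Negative eigenvalues of the
    centered Gram matrix (non-Euclidean distances) are truncated to zero
    for coordinates and reported in ``negative_eigenvalues``.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    negative_eigenvalues: np.ndarray

    @property
    def proportion_explained(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        return self.eigenvalues / total if total > 0 else self.eigenvalues


def pcoa(distances: pd.DataFrame, n_axes: int = 2) -> PCoAResult:
    """Principal coordinates analysis (classical metric scaling).

    Eigendecomposition of -0.5 * J D^2 J where J is the centering matrix.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValidationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValidationError("distance matrix must have a zero diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh(gram)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    negative = eigvals[eigvals < 0]
    eigvals = np.clip(eigvals, 0.0, None)
    n_axes = min(n_axes, n)
    coords = eigvecs[:, :n_axes] * np.sqrt(eigvals[:n_axes])
    index = distances.index if isinstance(distances, pd.DataFrame) else range(n)
    frame = pd.DataFrame(
        coords, index=index, columns=[f"PCo{i + 1}" for i in range(n_axes)]
    )
    return PCoAResult(frame, eigvals, negative)


def condition_divergence(ra: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis distance of each culture to its own experiment's inoculum.

    Returns one record per culture sample, sorted by descending distance
    (ties broken lexicographically by condition label).
    """
    cultures = [s for s in metadata.index[metadata["role"] == "culture"] if s in ra.columns]
    inocula = [s for s in metadata.index[metadata["role"] == "inoculum"] if s in ra.columns]
    inoculum_of_exp = {metadata.loc[s, "experiment_id"]: s for s in inocula}
    rows = []
    for s in cultures:
        exp = metadata.loc[s, "experiment_id"]
        if exp not in inoculum_of_exp:
            raise ValidationError(f"experiment {exp!r} has no inoculum sample in the table")
        inoc = inoculum_of_exp[exp]
        dist = 1.0 - np.minimum(ra[s].to_numpy(), ra[inoc].to_numpy()).sum()
        rows.append(
            {
                "condition": metadata.loc[s, "condition"],
                "category": metadata.loc[s, "category"],
                "experiment_id": exp,
                "sample_id": s,
                "bray_curtis": float(dist),
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["bray_curtis", "condition"], ascending=[False, True], ignore_index=True
    )
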