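"""Population graphs over imaging scans.

Two kinds of graph carry all cross-sample information into the graph
convolutions:

* the population scan graph (PSG), built from pairwise Pearson similarity of
  vectorized connectivity matrices, min-max normalized, shifted by +1 and
  fused multiplicatively across imaging modalities, so every entry lies in
  [1, 2^M];
* the population omics graph (POG), built from subject-level Pearson
  correlation of one omics type's feature vectors, self-looped, rescaled with
  the unsigned WGCNA soft threshold |r|^beta and expanded from subjects to
  scans by block duplication, so every entry lies in [0, 1] with a unit
  diagonal.

Scan order is the manifest order everywhere; nothing here sorts implicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScanManifest",
    "ConnectivityFeatures",
    "OmicsTable",
    "PopulationGraph",
    "pearson_similarity",
    "pairwise_pearson",
    "build_psg",
    "wgcna_power_scale",
    "pick_soft_threshold",
    "duplicate_scans",
    "build_pog",
]

_SYMMETRY_TOL = 1e-12


@dataclass(frozen=True)
class ScanManifest:
    """The cohort roster: scans, their subjects, class labels.

    Rows are aligned across ``scan_ids``, ``subject_ids``, ``labels``,
    ``is_augmented`` and, when present, ``modalities_present``.  Labels are
    class indices (0 = healthy control, 1 = disease for the binary task).
    """

    scan_ids: tuple[str, ...]
    subject_ids: tuple[str, ...]
    labels: tuple[int, ...]
    is_augmented: tuple[bool, ...] = ()
    modalities_present: tuple[frozenset, ...] = ()

    def __post_init__(self):
        n = len(self.scan_ids)
        if len(set(self.scan_ids)) != n:
            raise ValueError("scan_ids must be unique")
        if len(self.subject_ids) != n or len(self.labels) != n:
            raise ValueError("manifest columns must have equal length")
        if not self.is_augmented:
            object.__setattr__(self, "is_augmented", tuple(False for _ in range(n)))
        elif len(self.is_augmented) != n:
            raise ValueError("is_augmented must match scan count")
        # one subject per scan is structural; one label per subject must hold too
        seen: dict[str, int] = {}
        for sid, lab in zip(self.subject_ids, self.labels):
            if sid in seen and seen[sid] != lab:
                raise ValueError(f"subject {sid!r} carries conflicting labels")
            seen[sid] = lab

    @property
    def n_scans(self) -> int:
        return len(self.scan_ids)

    def subjects(self) -> tuple[str, ...]:
        """Unique subjects in order of first appearance."""
        out, seen = [], set()
        for sid in self.subject_ids:
            if sid not in seen:
                seen.add(sid)
                out.append(sid)
        return tuple(out)

    def subject_labels(self) -> dict[str, int]:
        return {s: l for s, l in zip(self.subject_ids, self.labels)}

    def require_two_classes(self) -> None:
        if len(set(self.labels)) < 2:
            raise ValueError("both classes must be present to train a model")


@dataclass(frozen=True)
class ConnectivityFeatures:
    """Vectorized connectivity features for one imaging modality.

    ``matrix`` is P x J_m where each row is the strict upper triangle
    (row-major, i < j, 0-based regions) of an R x R symmetric connectivity
    matrix, so J_m = R(R-1)/2.
    """

    modality: str
    matrix: np.ndarray
    atlas_size: int

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        r = self.atlas_size
        expected = r * (r - 1) // 2
        if m.ndim != 2 or m.shape[1] != expected:
            raise ValueError(
                f"modality {self.modality!r}: expected {expected} features for "
                f"a {r}-region atlas, got shape {m.shape}"
            )
        if not np.isfinite(m).all():
            raise ValueError(f"modality {self.modality!r}: non-finite features")

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class OmicsTable:
    """Subject-level feature table for one omics type (S x K_n)."""

    omics_type: str
    matrix: np.ndarray
    subject_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape != (len(self.subject_ids), len(self.feature_ids)):
            raise ValueError(f"omics {self.omics_type!r}: shape/id mismatch")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError(f"omics {self.omics_type!r}: duplicate subject_ids")
        if m.shape[1] < 1:
            raise ValueError(f"omics {self.omics_type!r}: needs >=1 feature")
        if not np.isfinite(m).all():
            raise ValueError(f"omics {self.omics_type!r}: missing/non-finite values")

    def row_for(self, subject_id: str) -> np.ndarray:
        try:
            return self.matrix[self.subject_ids.index(subject_id)]
        except ValueError:
            raise KeyError(f"subject {subject_id!r} absent from omics "
                           f"{self.omics_type!r}") from None


@dataclass
class PopulationGraph:
    """A dense P x P weighted similarity graph over scans (PSG or POG)."""

    kind: str  # "PSG" | "POG"
    adjacency: np.ndarray
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        a = np.asarray(self.adjacency, dtype=float)
        self.adjacency = a
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.isfinite(a).all():
            raise ValueError("adjacency must be finite")
        if np.abs(a - a.T).max(initial=0.0) > _SYMMETRY_TOL:
            raise ValueError("adjacency must be symmetric")

    @property
    def n_scans(self) -> int:
        return self.adjacency.shape[0]


def pearson_similarity(x_u, x_v) -> float:
    """Sample Pearson correlation of two feature vectors.

    A zero-variance vector yields similarity 0 rather than an exception:
    degenerate scans must not abort cohort-graph construction.
    """
    x_u = np.asarray(x_u, dtype=float)
    x_v = np.asarray(x_v, dtype=float)
    if x_u.shape != x_v.shape or x_u.ndim != 1 or x_u.size < 2:
        raise ValueError("vectors must be 1-D, equal length >= 2")
    du = x_u - x_u.mean()
    dv = x_v - x_v.mean()
    denom = np.sqrt((du @ du) * (dv @ dv))
    if denom == 0.0:
        return 0.0
    return float(np.clip((du @ dv) / denom, -1.0, 1.0))


def pairwise_pearson(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All pairwise Pearson correlations of the rows of ``x``.

    Returns ``(C, degenerate)`` where ``degenerate`` marks zero-variance rows
    whose similarities (including the self-similarity) were set to 0.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    ok = x.std(axis=1) > 0
    c = np.zeros((n, n))
    k = int(ok.sum())
    if k == 1:
        c[np.ix_(ok, ok)] = 1.0
    elif k > 1:
        c[np.ix_(ok, ok)] = np.corrcoef(x[ok])
    c = np.clip(c, -1.0, 1.0)
    c = (c + c.T) / 2.0
    return c, ~ok


def _minmax_plus_one(c: np.ndarray) -> np.ndarray:
    """Min-max normalize over ALL entries (diagonal included), then add 1.

    A constant matrix (max == min) maps to all-zeros, giving the all-ones
    factor after +1 — a fusion identity for an information-free modality.
    """
    lo, hi = c.min(), c.max()
    if hi == lo:
        return np.ones_like(c)
    return (c - lo) / (hi - lo) + 1.0


def build_psg(features: list[ConnectivityFeatures]) -> PopulationGraph:
    """Fuse per-modality scan-similarity graphs into the PSG.

    Per modality: pairwise Pearson similarities -> min-max to [0, 1] ->
    +1 (range [1, 2]) -> elementwise product into the accumulator, which is
    initialized as the all-ones matrix.  Entries end up in [1, 2^M].
    """
    if not features:
        raise ValueError("need at least one imaging modality")
    p = features[0].n_scans
    prov = []
    a = np.ones((p, p))
    for feat in features:
        if feat.n_scans != p:
            raise ValueError(
                f"modality {feat.modality!r} has {feat.n_scans} scans, expected {p}"
            )
        c, degenerate = pairwise_pearson(feat.matrix)
        if degenerate.any():
            prov.append(
                f"{feat.modality}: zero-variance scans at rows "
                f"{np.flatnonzero(degenerate).tolist()} -> similarity 0"
            )
        a = a * _minmax_plus_one(c)
        prov.append(f"{feat.modality}: pearson -> minmax -> +1 -> product")
    a = (a + a.T) / 2.0
    return PopulationGraph("PSG", a, prov)


def wgcna_power_scale(similarity: np.ndarray, beta: float) -> np.ndarray:
    """Unsigned WGCNA soft-threshold adjacency ``|s|**beta``.

    Order-preserving on |s|; with beta = 1 it is the identity on nonnegative
    input.  Graph-convolution normalization requires nonnegative weights,
    hence the unsigned variant.
    """
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    s = np.asarray(similarity, dtype=float)
    return np.abs(s) ** beta


def _scale_free_fit(adjacency: np.ndarray, n_bins: int = 8) -> float:
    """Signed scale-free topology fit index of a weighted graph.

    Bins the connectivity (off-diagonal row sums), regresses log10 frequency
    on log10 mean connectivity, and returns R^2 signed by -slope (a power-law
    degree distribution has negative slope).  NaN when the fit is undefined
    (fewer than 5 populated bins, or degenerate connectivity).
    """
    a = np.asarray(adjacency, dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    if k.max() <= 0 or np.ptp(k) == 0:
        return float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.any():
            mk = k[mask].mean()
            if mk > 0:
                xs.append(np.log10(mk))
                ys.append(np.log10(mask.sum() / k.size))
    if len(xs) < 5:
        return float("nan")
    xs, ys = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(xs, ys, 1)
    resid = ys - (slope * xs + intercept)
    ss_tot = ((ys - ys.mean()) ** 2).sum()
    if ss_tot == 0:
        return float("nan")
    r2 = 1.0 - (resid**2).sum() / ss_tot
    return float(-np.sign(slope) * r2)


DEFAULT_BETA = 6.0  # WGCNA's published unsigned-network default


def pick_soft_threshold(
    similarity: np.ndarray,
    candidate_betas,
    fit_threshold: float = 0.8,
) -> float:
    """Smallest candidate power whose scaled graph is approximately scale-free.

    Follows the WGCNA convention: accept the smallest beta with signed
    scale-free fit R^2 >= ``fit_threshold``; if none qualifies, return the
    candidate maximizing the fit.  Deterministic.  With fewer than 10 nodes
    the fit is meaningless and the fixed default beta = 6 is returned with a
    warning; likewise when the fit is undefined for every candidate.
    """
    candidates = sorted(float(b) for b in candidate_betas)
    if not candidates:
        raise ValueError("need at least one candidate beta")
    if len(candidates) == 1:
        return candidates[0]
    s = np.asarray(similarity, dtype=float)
    if s.shape[0] < 10:
        warnings.warn(
            f"only {s.shape[0]} nodes: too few to fit a degree distribution; "
            f"falling back to beta={DEFAULT_BETA}",
            stacklevel=2,
        )
        return DEFAULT_BETA
    fits = [(_scale_free_fit(wgcna_power_scale(s, b)), b) for b in candidates]
    for fit, b in fits:
        if np.isfinite(fit) and fit >= fit_threshold:
            return b
    finite = [(fit, b) for fit, b in fits if np.isfinite(fit)]
    if not finite:
        warnings.warn(
            f"scale-free fit undefined for all candidates; falling back to "
            f"beta={DEFAULT_BETA}",
            stacklevel=2,
        )
        return DEFAULT_BETA
    best_fit = max(fit for fit, _ in finite)
    return min(b for fit, b in finite if fit == best_fit)


def duplicate_scans(
    subject_graph: np.ndarray,
    subject_ids,
    manifest: ScanManifest,
) -> np.ndarray:
    """Expand an S x S subject graph to P x P scans by block duplication.

    Entry (p, q) of the output equals entry (subj(p), subj(q)) of the input;
    a subject with k scans induces a k x k constant block.  Scan order is the
    manifest order.
    """
    g = np.asarray(subject_graph, dtype=float)
    subject_ids = list(subject_ids)
    if g.shape != (len(subject_ids), len(subject_ids)):
        raise ValueError("subject graph shape must match subject_ids")
    pos = {s: i for i, s in enumerate(subject_ids)}
    idx = []
    for scan, subj in zip(manifest.scan_ids, manifest.subject_ids):
        if subj not in pos:
            raise KeyError(
                f"scan {scan!r}: subject {subj!r} lacks omics data; "
                "pre-filter the cohort to subjects with complete omics"
            )
        idx.append(pos[subj])
    idx = np.asarray(idx)
    return g[np.ix_(idx, idx)]


def build_pog(
    omics: OmicsTable,
    manifest: ScanManifest,
    beta: float | str = DEFAULT_BETA,
    candidate_betas=tuple(range(1, 13)),
) -> PopulationGraph:
    """Build the POG for one omics type.

    Subject-level Pearson correlations -> diagonal forced to exactly 1
    (self-loops, a fixed point of the powering) -> unsigned WGCNA scaling ->
    scan duplication.  ``beta`` is either a fixed power or ``"scale-free"``
    to select one with :func:`pick_soft_threshold`.
    """
    subjects = manifest.subjects()
    rows = np.vstack([omics.row_for(s) for s in subjects])
    c, degenerate = pairwise_pearson(rows)
    np.fill_diagonal(c, 1.0)
    prov = [f"{omics.omics_type}: subject pearson + self-loops"]
    if degenerate.any():
        prov.append(
            f"{omics.omics_type}: zero-variance subjects "
            f"{[subjects[i] for i in np.flatnonzero(degenerate)]} -> similarity 0"
        )
    if beta == "scale-free":
        beta_val = pick_soft_threshold(c, candidate_betas)
        prov.append(f"scale-free soft threshold: beta={beta_val}")
    else:
        beta_val = float(beta)
        prov.append(f"fixed soft threshold: beta={beta_val}")
    w = wgcna_power_scale(c, beta_val)
    a = duplicate_scans(w, subjects, manifest)
    a = (a + a.T) / 2.0
    prov.append("duplicated subject graph to scans")
    graph = PopulationGraph("POG", a, prov)
    if a.min() < 0 or a.max() > 1 or np.abs(np.diag(a) - 1.0).max() > _SYMMETRY_TOL:
        raise AssertionError("POG invariant violated: entries in [0,1], diag 1")
    return graph
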