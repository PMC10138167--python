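"""Relative qPCR quantification by the efficiency-corrected (Pfaffl) method.

A ``CtTable`` holds raw threshold cycles per (gene, sample, biological
replicate, technical replicate) together with per-gene amplification
efficiencies E (fold amplification per cycle, in (1, 2]) and the reference
gene used for normalisation. ``build_matrix`` averages technical replicates
within each biological replicate, then biological replicates, and converts
Ct values into log2 relative expression against a calibrator sample:

    ratio = E_target^dCt_target / E_ref^dCt_ref,   dCt = Ct(calibrator) - Ct(sample)

Cells not detected (missing Ct) are masked, never imputed as zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform


@dataclass
class CtTable:
    """Raw Ct values plus efficiencies and the reference-gene id.

    ``data`` columns: gene, sample, bio_rep, tech_rep, ct (NaN = not
    detected). ``efficiencies`` maps gene -> E; genes absent from the map
    default to 2.0 (perfect doubling). ``design`` optionally maps sample ->
    arbitrary metadata (organ / stress / timepoint) and is carried through
    untouched.
    """

    data: pd.DataFrame
    reference_gene: str
    efficiencies: dict = field(default_factory=dict)
    design: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"gene", "sample", "bio_rep", "tech_rep", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table missing columns: {sorted(missing)}")
        for gene, e in self.efficiencies.items():
            if not 1.0 < e <= 2.0:
                raise ValueError(f"efficiency for {gene} must lie in (1, 2], got {e}")
        ref = self.data[self.data["gene"] == self.reference_gene]
        samples = set(self.data["sample"])
        ref_samples = set(ref.loc[ref["ct"].notna(), "sample"])
        if samples - ref_samples:
            raise ValueError(
                f"reference gene {self.reference_gene!r} not detected in "
                f"samples {sorted(samples - ref_samples)}"
            )

    def efficiency(self, gene: str) -> float:
        return self.efficiencies.get(gene, 2.0)

    def mean_ct(self) -> pd.DataFrame:
        """Gene x sample mean Ct: technical reps averaged within each
        biological replicate, then biological replicates averaged."""
        per_bio = (
            self.data.groupby(["gene", "sample", "bio_rep"])["ct"]
            .mean()  # NaN if all tech reps missing
            .reset_index()
        )
        return per_bio.groupby(["gene", "sample"])["ct"].mean().unstack("sample")


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 relative expression with a not-detected mask."""

    values: pd.DataFrame  # log2 ratios; NaN where masked
    mask: pd.DataFrame    # True = not detected / unusable
    calibrator: str


def pfaffl_ratio(e_target: float, dct_target: float,
                 e_ref: float, dct_ref: float) -> float:
    """Efficiency-corrected expression ratio E_t^dCt_t / E_ref^dCt_ref.

    With both efficiencies equal to 2 this reduces exactly to the classic
    2^ddCt formula.
    """
    for label, v in (("e_target", e_target), ("e_ref", e_ref),
                     ("dct_target", dct_target), ("dct_ref", dct_ref)):
        if not np.isfinite(v):
            raise ValueError(f"{label} must be finite, got {v}")
    if not (1.0 < e_target <= 2.0 and 1.0 < e_ref <= 2.0):
        raise ValueError("efficiencies must lie in (1, 2]")
    return e_target ** dct_target / e_ref ** dct_ref


def build_matrix(ct: CtTable, calibrator: str) -> ExpressionMatrix:
    """Log2 relative expression of every gene/sample against a calibrator.

    Genes not detected in a sample are masked there; a gene not detected
    in the calibrator is masked everywhere, with a warning.
    """
    mean_ct = ct.mean_ct()
    if calibrator not in mean_ct.columns:
        raise ValueError(f"calibrator sample {calibrator!r} not in table")
    genes = [g for g in mean_ct.index if g != ct.reference_gene]
    samples = list(mean_ct.columns)
    ref_ct = mean_ct.loc[ct.reference_gene]
    e_ref = ct.efficiency(ct.reference_gene)

    values = pd.DataFrame(np.nan, index=genes, columns=samples)
    mask = pd.DataFrame(True, index=genes, columns=samples)
    for gene in genes:
        row = mean_ct.loc[gene]
        cal_ct = row[calibrator]
        if pd.isna(cal_ct):
            warnings.warn(
                f"gene {gene!r} not detected in calibrator {calibrator!r}; "
                "its relative values are masked", stacklevel=2,
            )
            continue
        e_t = ct.efficiency(gene)
        for sample in samples:
            if pd.isna(row[sample]):
                continue
            ratio = pfaffl_ratio(
                e_t, cal_ct - row[sample],
                e_ref, ref_ct[calibrator] - ref_ct[sample],
            )
            values.loc[gene, sample] = np.log2(ratio)
            mask.loc[gene, sample] = False
    values.index.name = mask.index.name = "gene"
    return ExpressionMatrix(values=values, mask=mask, calibrator=calibrator)


def call_regulation(matrix: ExpressionMatrix,
                    threshold: float = 1.0) -> pd.DataFrame:
    """Per-cell regulation call: up / down / nc / nd.

    ``up`` when log2 ratio >= threshold (closed boundary), ``down`` when
    <= -threshold, ``nc`` (no change) otherwise, ``nd`` where masked.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    calls = pd.DataFrame("nc", index=matrix.values.index,
                         columns=matrix.values.columns)
    calls = calls.mask(matrix.values >= threshold, "up")
    calls = calls.mask(matrix.values <= -threshold, "down")
    calls = calls.mask(matrix.mask, "nd")
    return calls


def _pairwise_complete_distances(values: np.ndarray) -> np.ndarray:
    """Euclidean distance over cells unmasked in both profiles.

    Entries are NaN when fewer than 2 cells are shared.
    """
    n = values.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~np.isnan(values[i]) & ~np.isnan(values[j])
            if shared.sum() < 2:
                d[i, j] = d[j, i] = np.nan
            else:
                diff = values[i, shared] - values[j, shared]
                d[i, j] = d[j, i] = float(np.sqrt(np.sum(diff ** 2)))
    return d


def hierarchical_cluster(matrix: ExpressionMatrix, method: str = "average"):
    """Agglomerative clustering of gene profiles; (linkage, leaf ids).

    Distances are Euclidean over pairwise-complete (unmasked in both)
    cells. Profiles that cannot be placed (fewer than 2 shared unmasked
    cells against some retained profile) are dropped with a warning,
    later input order first. Ties in the agglomeration are broken by
    scipy's deterministic ordering of the condensed matrix.
    """
    ids = list(matrix.values.index)
    vals = matrix.values.to_numpy(dtype=float)
    d = _pairwise_complete_distances(vals)
    keep = list(range(len(ids)))
    while True:
        sub = d[np.ix_(keep, keep)]
        bad = np.isnan(sub).sum(axis=1)
        if not bad.any():
            break
        worst = int(np.argmax(bad[::-1]))  # later input order first on ties
        worst = len(keep) - 1 - worst
        warnings.warn(
            f"profile {ids[keep[worst]]!r} excluded from clustering: too few "
            "shared unmasked cells", stacklevel=2,
        )
        keep.pop(worst)
    if len(keep) < 2:
        raise ValueError("need at least 2 clusterable profiles")
    sub = d[np.ix_(keep, keep)]
    Z = linkage(squareform(sub, checks=False), method=method)
    order = [ids[keep[i]] for i in leaves_list(Z)]
    return Z, order, [ids[i] for i in keep]


def linkage_to_newick(Z: np.ndarray, labels) -> str:
    """Serialize a scipy linkage matrix as a Newick string (heights as
    branch lengths from merge height to children)."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: str(labels[i]) for i in range(n)}
    for k, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = h - heights[a]
        lb = h - heights[b]
        nodes[n + k] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[n + k] = h
    return nodes[n + len(Z) - 1] + ";"
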