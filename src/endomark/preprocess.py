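"""Probe-to-gene collapsing and a simplified cross-platform adjustment.

Expression arrays report multiple probes per gene; gene-level values are the
arithmetic mean across a gene's probes, per sample, with unmapped probes
dropped (and counted).  Samples assayed on different array designs are then
put on a common scale by a per-gene location–scale adjustment: within each
platform a gene's values are centered and scaled to the pooled mean and
pooled SD.  This is a deliberately simple stand-in for empirical-Bayes batch
correction (the full ComBat machinery, which shrinks the per-gene batch
parameters across genes, is an extension point); it removes pure location and
scale platform biases exactly and preserves within-platform rank order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ProbeMatrix", "collapse_probes", "adjust_platforms"]

logger = logging.getLogger(__name__)


@dataclass
class ProbeMatrix:
    """Probe-level expression: probes in rows, samples in columns."""

    values: pd.DataFrame  # index: probe ids, columns: sample ids
    probe_to_gene: dict[str, str]  # unmapped probes absent or mapped to None

    def __post_init__(self) -> None:
        if self.values.empty:
            raise ValueError("empty probe matrix")


def collapse_probes(m: ProbeMatrix) -> pd.DataFrame:
    """Collapse probe rows to gene rows by per-sample averaging.

    Unmapped probes are dropped; the count is logged.  Returns a gene×sample
    DataFrame sorted by gene symbol.
    """
    genes = pd.Series(
        [m.probe_to_gene.get(p) for p in m.values.index], index=m.values.index
    )
    unmapped = genes.isna()
    if unmapped.all():
        raise ValueError("no probe maps to a gene")
    if unmapped.any():
        logger.info("dropping %d unmapped probes", int(unmapped.sum()))
    mapped = m.values[~unmapped]
    return mapped.groupby(genes[~unmapped]).mean().sort_index()


def adjust_platforms(gene_matrix: pd.DataFrame, platform_labels) -> pd.DataFrame:
    """Per-gene location–scale standardization of platforms to the pooled scale.

    For each gene, each platform's values are centered at the pooled mean and
    scaled so their SD equals the pooled SD.  A platform with fewer than 2
    samples is center-only (no scale estimate), with a warning.  A single
    platform comes back unchanged.
    """
    labels = pd.Series(np.asarray(platform_labels), index=gene_matrix.columns)
    platforms = labels.unique()
    if len(platforms) == 1:
        return gene_matrix.copy()
    X = gene_matrix.to_numpy(dtype=float)
    pooled_mean = X.mean(axis=1)
    pooled_sd = X.std(axis=1, ddof=1)
    out = np.empty_like(X)
    for plat in platforms:
        cols = (labels == plat).to_numpy()
        block = X[:, cols]
        mu = block.mean(axis=1)
        if cols.sum() < 2:
            warnings.warn(
                f"platform {plat!r} has <2 samples; centering only, no rescaling"
            )
            out[:, cols] = block - mu[:, None] + pooled_mean[:, None]
            continue
        sd = block.std(axis=1, ddof=1)
        scale = np.where((sd > 0) & (pooled_sd > 0), pooled_sd / np.where(sd > 0, sd, 1.0), 1.0)
        out[:, cols] = (block - mu[:, None]) * scale[:, None] + pooled_mean[:, None]
    return pd.DataFrame(out, index=gene_matrix.index, columns=gene_matrix.columns)
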