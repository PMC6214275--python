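"""Per-neuron statistical thresholding of correlation matrices.

Every neuron ``j`` gets an outward threshold from the statistics of its
``n-1`` outgoing values and an inward threshold from its ``n-1`` incoming
values (diagonal excluded):

    ``gamma_out(j) = mu_out(j) + kappa * sigma_out(j)``
    ``gamma_in(j)  = mu_in(j)  + kappa * sigma_in(j)``

with population standard deviations. The directed correlation ``j -> i``
is significant with respect to ``kappa`` iff

    ``C[i, j] >= max(gamma_out(j), gamma_in(i))``,

a non-strict comparison, so in the degenerate all-equal case every edge is
retained. Undefined (NaN) entries are treated as zero with a logged count.
Thresholds are monotone in ``kappa``, hence edge sets are nested across
increasing ``kappa``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["NeuronThresholds", "FunctionalNetwork", "neuron_thresholds", "apply_threshold"]


@dataclass
class NeuronThresholds:
    """Per-neuron outward/inward thresholds and their defining statistics."""

    gamma_out: np.ndarray
    gamma_in: np.ndarray
    mu_out: np.ndarray
    mu_in: np.ndarray
    sigma_out: np.ndarray
    sigma_in: np.ndarray
    kappa: float


@dataclass
class FunctionalNetwork:
    """Directed functional network from thresholding one correlation matrix.

    ``adjacency[i, j] == 1`` iff the ``j -> i`` correlation was retained;
    ``retained_values`` keeps the raw value where retained, zero elsewhere.
    """

    adjacency: np.ndarray
    kappa: float
    source_method: str
    retained_values: np.ndarray

    @property
    def n_neurons(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())


def _clean_values(C) -> tuple[np.ndarray, str]:
    method = getattr(C, "method", "unknown")
    values = np.asarray(getattr(C, "values", C), dtype=float).copy()
    if values.ndim != 2 or values.shape[0] != values.shape[1] or values.shape[0] < 2:
        raise ValueError("need a square correlation matrix with n >= 2")
    n_undef = int(np.isnan(values).sum())
    if n_undef:
        logger.warning("treating %d undefined correlation entries as 0", n_undef)
        values = np.nan_to_num(values, nan=0.0)
    np.fill_diagonal(values, 0.0)
    return values, method


def neuron_thresholds(C, kappa: float) -> NeuronThresholds:
    """Outward/inward mean + ``kappa``·SD thresholds per neuron.

    ``C`` is a :class:`~spikeplex.correlation.CorrelationMatrix` or a plain
    square matrix with the ``values[i, j] = j -> i`` convention. Statistics
    run over the ``n-1`` off-diagonal values of each column (outgoing) and
    row (incoming); SDs are population SDs.
    """
    values, _ = _clean_values(C)
    n = values.shape[0]
    off = ~np.eye(n, dtype=bool)
    # outgoing values of neuron j live in column j, incoming values of i in row i
    mu_out = np.array([values[off[:, j], j].mean() for j in range(n)])
    mu_in = np.array([values[i, off[i, :]].mean() for i in range(n)])
    sigma_out = np.array([values[off[:, j], j].std() for j in range(n)])
    sigma_in = np.array([values[i, off[i, :]].std() for i in range(n)])
    return NeuronThresholds(
        gamma_out=mu_out + kappa * sigma_out,
        gamma_in=mu_in + kappa * sigma_in,
        mu_out=mu_out,
        mu_in=mu_in,
        sigma_out=sigma_out,
        sigma_in=sigma_in,
        kappa=kappa,
    )


def apply_threshold(
    C, kappa: float, thresholds: NeuronThresholds | None = None
) -> FunctionalNetwork:
    """Retain the ``j -> i`` correlation iff it clears both endpoint thresholds.

    ``thresholds`` overrides the statistics computed from ``C`` itself
    (useful for re-applying a fixed rule to a filtered matrix).
    """
    values, method = _clean_values(C)
    th = thresholds if thresholds is not None else neuron_thresholds(values, kappa)
    bound = np.maximum(th.gamma_out[None, :], th.gamma_in[:, None])
    adj = (values >= bound).astype(np.uint8)
    np.fill_diagonal(adj, 0)
    return FunctionalNetwork(
        adjacency=adj,
        kappa=kappa,
        source_method=method,
        retained_values=np.where(adj.astype(bool), values, 0.0),
    )
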