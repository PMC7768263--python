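"""Normalized polymerase-occupancy tracks from fragment counts.

The occupancy signal is the per-fragment log2 ratio of a polymerase–Dam
fusion library over a freely diffusing Dam control.  The control profile
measures chromatin accessibility and sequencing depth at once, so the
ratio cancels both and what remains is interpreted as cumulative
polymerase footprint since the last DNA replication.

Two scalings are offered: plain library-size (total-count) scaling, the
default, and an optional kernel-density recentering that subtracts the
mode of the score distribution — useful when most fragments are unbound
and the bulk of the distribution should sit at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .amplicons import FragmentCounts


@dataclass
class NormParams:
    """Normalization parameters.

    ``pseudocount`` is on the counts-per-million scale (default 0.5 CPM),
    applied to both libraries after depth scaling so that zero-count
    fragments stay finite.  ``chip_pseudocount`` (default 8, in raw count
    units) is used only by the ChIP-style comparison path
    (:func:`chip_log2_ratio`), where pseudocounts are added to
    depth-equalized raw counts rather than CPM.
    """

    pseudocount: float = 0.5
    scaling: str = "library_size"
    chip_pseudocount: float = 8.0

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.scaling not in ("library_size", "kde_mode"):
            raise ValueError(f"unknown scaling {self.scaling!r}")


@dataclass
class OccupancyTrack:
    """Per-fragment log2(fusion/control) scores."""

    fragments: pd.DataFrame = field(repr=False)
    scores: np.ndarray = field(repr=False)
    library_pair: tuple[str, str] = ("fusion", "control")

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.scores) != len(self.fragments):
            raise ValueError("score vector length != fragment count")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("occupancy scores must be finite")


def _kde_mode(x: np.ndarray) -> float:
    kde = stats.gaussian_kde(x)
    grid = np.linspace(x.min(), x.max(), 2048)
    return float(grid[np.argmax(kde(grid))])


def normalize_counts(
    fusion: FragmentCounts,
    control: FragmentCounts,
    params: NormParams | None = None,
    fragments: pd.DataFrame | None = None,
) -> OccupancyTrack:
    """log2 fusion/control occupancy per fragment.

    Each library is scaled to its total; a pseudocount (CPM units) is
    added to both before the ratio:

        score_i = log2( (f_i/F + psi) / (c_i/C + psi) )

    so the track is invariant to sequencing depth and antisymmetric
    under swapping the two libraries.  With ``scaling="kde_mode"`` the
    kernel-density mode of the score distribution is then subtracted.
    """
    params = params or NormParams()
    f = np.asarray(fusion.counts, dtype=float)
    c = np.asarray(control.counts, dtype=float)
    if f.shape != c.shape:
        raise ValueError(
            f"fragment lists differ: fusion has {f.size}, control has {c.size}"
        )
    F, C = f.sum(), c.sum()
    if F == 0 or C == 0:
        raise ValueError("zero-total library")
    psi = params.pseudocount / 1e6
    # difference of logs (not log of ratio) so a fusion/control swap
    # negates every score exactly, to the last bit
    scores = np.log2(f / F + psi) - np.log2(c / C + psi)
    if params.scaling == "kde_mode":
        scores = scores - _kde_mode(scores)
    if fragments is None:
        fragments = pd.DataFrame(
            {"chrom": "?", "start": 0, "end": 0, "fragment_id": np.arange(f.size)}
        )
    return OccupancyTrack(
        fragments=fragments,
        scores=scores,
        library_pair=(fusion.library_id, control.library_id),
    )


def correlate_tracks(a, b) -> float | None:
    """Pearson correlation between two per-fragment score vectors.

    Accepts :class:`OccupancyTrack` or plain vectors.  Returns None
    (with a warning) when either vector has zero variance.
    """
    x = np.asarray(a.scores if isinstance(a, OccupancyTrack) else a, dtype=float)
    y = np.asarray(b.scores if isinstance(b, OccupancyTrack) else b, dtype=float)
    if x.shape != y.shape:
        raise ValueError("tracks have different lengths")
    if x.size < 3:
        raise ValueError("need at least 3 fragments to correlate")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance in a track; correlation undefined")
        return None
    return float(stats.pearsonr(x, y).statistic)


def chip_log2_ratio(
    sample: np.ndarray,
    input_: np.ndarray,
    params: NormParams | None = None,
    reference_total: float = 1e6,
) -> np.ndarray:
    """ChIP-style log2(sample/input) over fixed bins.

    Both coverage vectors are scaled to a common reference total before a
    raw-count pseudocount (default 8) is added:

        score_i = log2( (s_i * D + 8) / (i_i * D' + 8) )

    with ``D = reference_total / sum(s)`` and likewise ``D'``.  Scaling
    to a fixed reference makes the result invariant to sequencing depth.
    """
    params = params or NormParams()
    s = np.asarray(sample, dtype=float)
    i = np.asarray(input_, dtype=float)
    if s.shape != i.shape:
        raise ValueError("sample and input binnings differ")
    S, I = s.sum(), i.sum()
    if S == 0 or I == 0:
        raise ValueError("zero-total coverage")
    pc = params.chip_pseudocount
    return np.log2((s * (reference_total / S) + pc) / (i * (reference_total / I) + pc))
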