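"""Global histogram thresholds: Huang fuzzy entropy, intermodes, intermeans.

All three operate on a 256-bin histogram of the image rescaled between its
minimum and maximum, and return a threshold in original intensity units
(the upper edge semantics: foreground is ``image > threshold``).  The
bin-level routines are exposed separately so they can be checked against
independent references on raw histograms.

* Huang — minimises a fuzzy-entropy measure of membership: pixels far from
  their class mean are "fuzzier" and contribute more entropy.
* Intermodes — iteratively smooths the histogram with a 3-bin mean filter
  until exactly two local maxima remain; the threshold is the midpoint of
  the two modes.  Assumes the histogram is reducible to bimodal.
* Intermeans (iterative, a.k.a. isodata/Ridler–Calvard) — iterates
  ``t <- (mean below t + mean above t) / 2`` to a fixed point.
"""

from __future__ import annotations

import numpy as np

from .errors import BimodalityError, ConstantImageError

__all__ = [
    "huang_threshold",
    "intermodes_threshold",
    "intermeans_threshold",
    "huang_threshold_bin",
    "intermodes_threshold_bin",
    "intermeans_threshold_bin",
    "image_histogram",
]

N_BINS = 256


def image_histogram(image: np.ndarray) -> tuple[np.ndarray, float, float]:
    """256-bin histogram of ``image`` over [min, max], plus the range."""
    image = np.asarray(image, dtype=np.float64)
    lo = float(image.min())
    hi = float(image.max())
    if hi <= lo:
        raise ConstantImageError("cannot threshold a constant image")
    hist, _ = np.histogram(image, bins=N_BINS, range=(lo, hi))
    return hist.astype(np.int64), lo, hi


def _bin_to_intensity(t_bin: int, lo: float, hi: float) -> float:
    # upper edge of bin t: values in bins <= t are background
    width = (hi - lo) / N_BINS
    return lo + (t_bin + 1) * width


def huang_threshold_bin(hist: np.ndarray) -> int:
    """Bin index minimising Huang's fuzzy entropy.

    For a candidate threshold ``t`` the background (bins <= t) and
    foreground (bins > t) class means are computed; each grey level's
    membership to its class is ``1 / (1 + |g - mu| / C)`` with ``C`` the
    grey-level range, and the Shannon entropy of the membership, weighted
    by the histogram, is the cost.  Ties take the lowest bin.
    """
    hist = np.asarray(hist, dtype=np.float64)
    nz = np.nonzero(hist)[0]
    if nz.size == 0:
        raise ConstantImageError("empty histogram")
    first, last = int(nz[0]), int(nz[-1])
    if first == last:
        raise ConstantImageError("histogram has a single occupied bin")
    C = last - first
    g = np.arange(hist.size, dtype=np.float64)
    w = hist * g
    s_cum = np.cumsum(hist)
    w_cum = np.cumsum(w)
    s_tot, w_tot = s_cum[-1], w_cum[-1]

    best_t, best_e = first, np.inf
    for t in range(first, last):
        s0 = s_cum[t]
        s1 = s_tot - s0
        if s0 == 0 or s1 == 0:
            continue
        mu0 = w_cum[t] / s0
        mu1 = (w_tot - w_cum[t]) / s1
        mu = np.empty(hist.size)
        mu[: t + 1] = 1.0 / (1.0 + np.abs(g[: t + 1] - mu0) / C)
        mu[t + 1 :] = 1.0 / (1.0 + np.abs(g[t + 1 :] - mu1) / C)
        # Shannon entropy of membership; mu in (0.5, 1] so 1-mu can be 0
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -mu * np.log(mu) - (1.0 - mu) * np.log(1.0 - mu)
        h[~np.isfinite(h)] = 0.0
        e = float(np.dot(hist, h))
        if e < best_e - 1e-12:
            best_e = e
            best_t = t
    return best_t


def _count_peaks(hist: np.ndarray) -> int:
    h = hist
    return int(np.sum((h[1:-1] > h[:-2]) & (h[1:-1] > h[2:])))


def intermodes_threshold_bin(hist: np.ndarray, max_iter: int = 10_000) -> int:
    """Midpoint of the two modes of the iteratively smoothed histogram.

    The histogram is repeatedly convolved with a centred 3-bin mean filter
    (edge bins average with one implicit zero neighbour) until exactly two
    strict local maxima remain.  Raises :class:`BimodalityError` if that
    never happens within ``max_iter`` passes.
    """
    h = np.asarray(hist, dtype=np.float64).copy()
    it = 0
    while _count_peaks(h) != 2:
        if it >= max_iter:
            raise BimodalityError(
                f"histogram not reducible to bimodal in {max_iter} smoothing passes"
            )
        h = np.convolve(h, np.ones(3) / 3.0, mode="same")
        it += 1
    peaks = np.nonzero((h[1:-1] > h[:-2]) & (h[1:-1] > h[2:]))[0] + 1
    return int((peaks[0] + peaks[1]) // 2)


def intermeans_threshold_bin(hist: np.ndarray, max_iter: int = 1_000) -> int:
    """Iterative intermeans (isodata) threshold bin."""
    hist = np.asarray(hist, dtype=np.float64)
    nz = np.nonzero(hist)[0]
    if nz.size < 2:
        raise ConstantImageError("histogram has fewer than two occupied bins")
    g = np.arange(hist.size, dtype=np.float64)
    t = int((nz[0] + nz[-1]) // 2)
    for _ in range(max_iter):
        s0 = hist[: t + 1].sum()
        s1 = hist[t + 1 :].sum()
        if s0 == 0:
            t += 1
            continue
        if s1 == 0:
            t -= 1
            continue
        mu0 = (hist[: t + 1] * g[: t + 1]).sum() / s0
        mu1 = (hist[t + 1 :] * g[t + 1 :]).sum() / s1
        t_new = int(np.floor((mu0 + mu1) / 2.0))
        if t_new == t:
            return t
        t = t_new
    return t


def huang_threshold(image: np.ndarray) -> float:
    """Huang fuzzy-entropy threshold of an image, in intensity units."""
    hist, lo, hi = image_histogram(image)
    return _bin_to_intensity(huang_threshold_bin(hist), lo, hi)


def intermodes_threshold(image: np.ndarray, max_iter: int = 10_000) -> float:
    """Intermodes threshold of an image, in intensity units."""
    hist, lo, hi = image_histogram(image)
    return _bin_to_intensity(intermodes_threshold_bin(hist, max_iter=max_iter), lo, hi)


def intermeans_threshold(image: np.ndarray) -> float:
    """Iterative intermeans threshold of an image, in intensity units."""
    hist, lo, hi = image_histogram(image)
    return _bin_to_intensity(intermeans_threshold_bin(hist), lo, hi)
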