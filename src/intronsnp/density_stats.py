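"""SNP-density profiles by distance-to-boundary and Kendall trend tests.

The density statistic: for each distance d in 1..W (W = 70 nt by default,
which covers the region of elevated and then plateauing density), count the
polymorphic sites whose nearest-boundary distance is exactly d, and divide by
the number of contributing units that possess a nucleotide at that nearest
distance. Short exons drop out of the denominator at large d, so the
denominator is adjusted per distance. Every site is counted once, at its
nearest boundary only.

Two denominator conventions are provided:

* ``exon_ends`` (default): the denominator is the number of exonic positions
  whose nearest-boundary distance equals d -- equivalently the number of
  (exon, boundary) pairs that possess such a position, since each pair has at
  most one. This is a true per-site density ("SNPs per site").
* ``exons``: the denominator is the number of exons possessing any position
  at nearest-distance d (the coarser per-exon normalization).

Monotone decay of density with distance is tested with Kendall's tau-b
(tie-corrected) over the per-distance (d, density) pairs, two-sided p from
the normal approximation; for very short profiles (n <= 8) an exact
permutation enumeration replaces the approximation. Profiles are stratified
by gene, intron mobility, intron group and boundary side, a site counting
only toward the stratum of its own nearest boundary.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .boundary_distance import distance_array
from .gene_models import FIVE_PRIME, GeneModel, IntronSiteSet

logger = logging.getLogger("intronsnp")

__all__ = [
    "DensityProfile",
    "SmoothedCurve",
    "TrendTestResult",
    "density_profile",
    "smooth",
    "kendall_trend",
    "stratified_trends",
]

DEFAULT_WINDOW = 70
SMOOTH_WINDOW = 10


@dataclass
class DensityProfile:
    """Per-distance SNP counts, denominators and densities for one stratum."""

    window: int
    snp_count: np.ndarray  # shape (window,), index d-1
    contrib: np.ndarray  # shape (window,)
    stratum: str = "all"
    denominator_convention: str = "exon_ends"
    n_excluded: int = 0  # sites without a distance (e.g. intronless gene)

    @property
    def distances(self) -> np.ndarray:
        return np.arange(1, self.window + 1)

    @property
    def density(self) -> np.ndarray:
        """snp_count / contrib, NaN where no unit contributes."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(
                self.contrib > 0, self.snp_count / self.contrib, np.nan
            )

    def defined(self) -> np.ndarray:
        return self.contrib > 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "distance": self.distances,
                "snp_count": self.snp_count,
                "contrib": self.contrib,
                "density": self.density,
                "stratum": self.stratum,
            }
        )


@dataclass
class SmoothedCurve:
    """Sliding-window mean of the density profile (10-nt window, 1-nt step).

    The curve starts at the center of the first window (x = 5.5 for a full
    profile), not at distance 0.
    """

    x: np.ndarray
    y: np.ndarray
    smooth_window: int = SMOOTH_WINDOW
    step: int = 1


@dataclass
class TrendTestResult:
    """Kendall tau-b of density against distance for one stratum."""

    tau: float
    p_two_sided: float
    n_points: int
    stratum: str = "all"
    degenerate: bool = False

    def __iter__(self):  # convenient (tau, p) unpacking
        return iter((self.tau, self.p_two_sided))


# ---------------------------------------------------------------------------
# Stratum machinery


def _as_mapping(models, intron_sites):
    """Normalize (models, intron_sites) to {gene_id: (model, site_set)}."""
    if isinstance(models, GeneModel):
        models = [models]
    out = {}
    for m in models:
        if isinstance(intron_sites, dict):
            ss = intron_sites.get(m.gene_id)
        elif isinstance(intron_sites, IntronSiteSet):
            if len(list(models)) > 1:
                raise ValueError(
                    "one IntronSiteSet given for several gene models"
                )
            ss = intron_sites
        else:
            ss = None
        out[m.gene_id] = (m, ss or IntronSiteSet.from_model(m))
    return out


def _mobility_label(mobile) -> str:
    if mobile is True:
        return "mobile"
    if mobile is False:
        return "immobile"
    return "unknown"


def _boundary_matches(stratum_filter, gene_id, intron, side) -> bool:
    if not stratum_filter:
        return True
    for key, value in stratum_filter.items():
        if key == "gene":
            if gene_id != value:
                return False
        elif key == "mobility":
            if _mobility_label(intron.mobile if intron else None) != value:
                return False
        elif key == "group":
            if (intron.group if intron else "unknown") != value:
                return False
        elif key == "side":
            if side != value:
                return False
        else:
            raise ValueError(f"unknown stratum key {key!r}")
    return True


def density_profile(sites, models, intron_sites=None, window: int = DEFAULT_WINDOW,
                    convention: str = "exon_ends",
                    stratum_filter: dict | None = None,
                    stratum_label: str | None = None) -> DensityProfile:
    """Build the per-distance density profile over one or more genes.

    ``sites`` must already carry distances computed against the same intron
    site sets (see :func:`intronsnp.boundary_distance.annotate_distances`).
    Sites with no distance (intronless gene) are excluded with a logged
    count. A ``stratum_filter`` restricts both numerator and denominator to
    positions whose *nearest* boundary matches, e.g.
    ``{"mobility": "mobile"}`` or ``{"gene": "cox1", "side": "5prime"}``.
    """
    if convention not in {"exon_ends", "exons"}:
        raise ValueError(f"unknown denominator convention {convention!r}")
    mapping = _as_mapping(models, intron_sites)

    snp_count = np.zeros(window, dtype=int)
    n_excluded = 0
    for s in sites:
        if s.context != "exonic":
            continue
        if s.distance is None:
            n_excluded += 1
            continue
        if s.gene_id not in mapping:
            raise ValueError(f"site at {s.ref_pos}: unknown gene {s.gene_id!r}")
        if not _site_matches(stratum_filter, s):
            continue
        if 1 <= s.distance <= window:
            snp_count[s.distance - 1] += 1
    if n_excluded:
        logger.info("density_profile: %d site(s) without distance excluded",
                    n_excluded)

    contrib = np.zeros(window, dtype=int)
    for gene_id, (model, ss) in mapping.items():
        da = distance_array(model, ss)
        if da is None:
            continue
        dist, is5, junc_idx = da
        sides = np.where(is5, FIVE_PRIME, "3prime")
        keep = np.ones(model.spliced_length, dtype=bool)
        if stratum_filter:
            for p in range(model.spliced_length):
                intr = ss.attrs[junc_idx[p]]
                keep[p] = _boundary_matches(
                    stratum_filter, gene_id, intr, str(sides[p])
                )
        if convention == "exon_ends":
            sel = keep & (dist >= 1) & (dist <= window)
            np.add.at(contrib, dist[sel] - 1, 1)
        else:  # exons: one count per exon possessing any position at d
            bounds = np.concatenate(
                ([0], np.asarray(model.junction_offsets(), dtype=int),
                 [model.spliced_length])
            )
            for lo, hi in zip(bounds[:-1], bounds[1:]):
                seen = set()
                for p in range(lo, hi):
                    d = dist[p]
                    if keep[p] and 1 <= d <= window and d not in seen:
                        seen.add(int(d))
                        contrib[d - 1] += 1
    return DensityProfile(
        window=window,
        snp_count=snp_count,
        contrib=contrib,
        stratum=stratum_label or _label_for(stratum_filter),
        denominator_convention=convention,
        n_excluded=n_excluded,
    )


def _site_matches(stratum_filter, site) -> bool:
    """Filter a site by its own recorded nearest-boundary attributes."""
    if not stratum_filter:
        return True
    for key, value in stratum_filter.items():
        if key == "gene":
            if site.gene_id != value:
                return False
        elif key == "mobility":
            if _mobility_label(site.nearest_mobile) != value:
                return False
        elif key == "group":
            if (site.nearest_group or "unknown") != value:
                return False
        elif key == "side":
            if site.side != value:
                return False
        else:
            raise ValueError(f"unknown stratum key {key!r}")
    return True


def _label_for(stratum_filter) -> str:
    if not stratum_filter:
        return "all"
    return ",".join(f"{k}={v}" for k, v in sorted(stratum_filter.items()))


# ---------------------------------------------------------------------------
# Smoothing


def smooth(profile: DensityProfile,
           smooth_window: int = SMOOTH_WINDOW) -> SmoothedCurve:
    """10-nt sliding-window mean over defined densities, 1-nt steps.

    Window k covers distances [k, k+smooth_window-1]; its x is the window
    center k + (smooth_window-1)/2. Windows with no defined density are
    omitted.
    """
    if smooth_window > profile.window:
        raise ValueError(
            f"smoothing window {smooth_window} exceeds profile window "
            f"{profile.window}"
        )
    if int(profile.defined().sum()) < smooth_window:
        raise ValueError(
            "profile has fewer defined densities than the smoothing window"
        )
    dens = profile.density
    ok = profile.defined()
    xs, ys = [], []
    for k in range(1, profile.window - smooth_window + 2):
        sl = slice(k - 1, k - 1 + smooth_window)
        if not ok[sl].any():
            continue
        xs.append(k + (smooth_window - 1) / 2.0)
        ys.append(float(np.nanmean(dens[sl])))
    return SmoothedCurve(
        x=np.asarray(xs), y=np.asarray(ys), smooth_window=smooth_window
    )


# ---------------------------------------------------------------------------
# Kendall trend test


def _tau_b(x, y):
    """Tie-corrected tau-b; NaN when a vector is wholly tied."""
    res = stats.kendalltau(x, y, variant="b")
    return float(res.statistic), float(res.pvalue)


def _exact_perm_p(x, y, tau_obs: float) -> float:
    """Exact two-sided p by enumerating all orderings of y (n <= 8)."""
    n = len(y)
    count = total = 0
    for perm in itertools.permutations(range(n)):
        yp = [y[i] for i in perm]
        t = stats.kendalltau(x, yp, variant="b").statistic
        total += 1
        if abs(t) >= abs(tau_obs) - 1e-12:
            count += 1
    return count / total


def kendall_trend(profile: DensityProfile, min_points: int = 10,
                  stratum: str | None = None) -> TrendTestResult:
    """Kendall tau-b of density against distance over defined distances.

    Distances with no contributing unit are excluded (no observable sites
    exist there), not zero-filled. A profile whose defined densities are all
    identical has no rank trend: tau is reported as 0 with p = 1 and the
    degenerate flag set.
    """
    ok = profile.defined()
    x = profile.distances[ok].astype(float)
    y = profile.density[ok]
    n = len(x)
    label = stratum if stratum is not None else profile.stratum
    if n < min_points:
        raise ValueError(
            f"trend test needs >= {min_points} defined distances, got {n}"
        )
    if np.all(y == y[0]):
        return TrendTestResult(0.0, 1.0, n, label, degenerate=True)
    if n <= 8:
        tau, _ = _tau_b(x, y)
        p = _exact_perm_p(list(x), list(y), tau)
    else:
        tau, p = _tau_b(x, y)
    if math.isnan(tau):
        return TrendTestResult(0.0, 1.0, n, label, degenerate=True)
    return TrendTestResult(tau, min(max(p, np.nextafter(0, 1)), 1.0), n, label)


STRATA_VALUES = {
    "mobility": ("mobile", "immobile", "unknown"),
    "group": ("I", "II", "spliceosomal", "unknown"),
    "side": (FIVE_PRIME, "3prime"),
}


def stratified_trends(sites, models, intron_sites=None,
                      strata_spec=("all",), window: int = DEFAULT_WINDOW,
                      convention: str = "exon_ends",
                      min_points: int = 10):
    """One trend test per stratum value plus the combined "all" stratum.

    ``strata_spec`` draws from {"gene", "mobility", "group", "side", "all"}.
    Strata with no sites or too few defined distances are skipped with a log
    entry. Returns (results, profiles) with matching order.
    """
    mapping = _as_mapping(models, intron_sites)
    filters: list[tuple[str, dict | None]] = []
    seen_all = False
    for key in strata_spec:
        if key == "all":
            seen_all = True
        elif key == "gene":
            for gid in mapping:
                filters.append((f"gene={gid}", {"gene": gid}))
        elif key in STRATA_VALUES:
            for v in STRATA_VALUES[key]:
                filters.append((f"{key}={v}", {key: v}))
        else:
            raise ValueError(f"unknown stratum key {key!r}")
    filters.append(("all", None))
    if not seen_all:
        pass  # "all" is always produced; listing it in strata_spec is a no-op

    results, profiles = [], []
    for label, filt in filters:
        prof = density_profile(
            sites, models, intron_sites, window=window,
            convention=convention, stratum_filter=filt, stratum_label=label,
        )
        if prof.snp_count.sum() == 0 and label != "all":
            logger.info("stratum %s: no sites, skipped", label)
            continue
        try:
            res = kendall_trend(prof, min_points=min_points, stratum=label)
        except ValueError:
            logger.info("stratum %s: too few defined distances, skipped",
                        label)
            continue
        results.append(res)
        profiles.append(prof)
    return results, profiles
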