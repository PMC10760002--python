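"""Ensemble statistics over replicated trajectories.

Conventions, applied uniformly:

* only post-burn-in ("analysis") frames enter any statistic; the default
  burn-in of 0.4 corresponds to analysing the last 3 µs of a 5 µs run;
* probability distributions pool all replicas (and, by default, both
  protomers of a dimer) before binning into 50 bins;
* state probabilities are computed per replica and reported as
  mean ± across-replica standard deviation (n−1 denominator);
* 2D densities are plain normalized joint histograms (total mass 1), not
  kernel estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .anchors import DEFAULT_ANCHORS, DEFAULT_THRESHOLDS, AnchorMap, Thresholds
from .errors import AlignmentError, EmptyInputError
from .structure import TrajectoryEnsemble
from . import metrics as _m
from . import fingerprint as _fp

#: metric identifiers accepted by :func:`compute_timeseries`
METRICS = {
    "alpha_c": ("alpha_c_position", "Å"),
    "ke": ("ke_min_distance", "Å"),
    "dfg": ("dfg_pseudo_dihedral", "deg"),
    "lig501": ("ligand_glu501_min_distance", "Å"),
}


@dataclass
class MetricTimeSeries:
    """Per-replica, per-frame, per-protomer values of one metric.

    ``values[r]`` has shape (n_analysis_frames, n_protomers); the protomer
    order is given by ``protomer_labels``.
    """

    ensemble_id: str
    metric_name: str
    units: str
    protomer_labels: tuple[str, ...]
    values: list[np.ndarray]

    def __post_init__(self):
        for r, v in enumerate(self.values):
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite metric values in replica {r}")

    @property
    def n_replicas(self) -> int:
        return len(self.values)

    def pooled(self, pool_protomers: bool = True) -> np.ndarray:
        """All analysis values pooled over replicas (and protomers)."""
        stacked = np.concatenate(self.values, axis=0)
        return stacked.ravel() if pool_protomers else stacked

    def protomer_series(self, label: str) -> "MetricTimeSeries":
        k = self.protomer_labels.index(label)
        return MetricTimeSeries(
            ensemble_id=self.ensemble_id,
            metric_name=self.metric_name,
            units=self.units,
            protomer_labels=(label,),
            values=[v[:, k:k + 1] for v in self.values],
        )


def compute_timeseries(
    ensemble: TrajectoryEnsemble,
    metric: str,
    anchors: AnchorMap = DEFAULT_ANCHORS,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    ligand: str | None = None,
    protomers: tuple[str, ...] | None = None,
) -> MetricTimeSeries:
    """Evaluate one named metric on every analysis frame of every replica.

    ``metric`` is one of ``"alpha_c"``, ``"ke"``, ``"dfg"`` or ``"lig501"``
    (the last requires ``ligand``: a residue name whose per-protomer copy is
    used, or a full ligand id applied to every protomer).
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(METRICS)}")
    topo = ensemble.topology
    labels = protomers or topo.protomer_labels()

    per_protomer_eval = []
    for label in labels:
        if metric == "alpha_c":
            ref, center = _m.alpha_c_atom_indices(topo, label, anchors)
            per_protomer_eval.append(
                lambda xyz, ref=ref, center=center: _m.centroid_distance(
                    xyz[:, ref], xyz[:, center]
                )
            )
        elif metric == "ke":
            nz, oxy = _m.ke_atom_indices(topo, label, anchors)
            per_protomer_eval.append(
                lambda xyz, nz=nz, oxy=oxy: _m.min_pair_distance(
                    xyz[:, [nz]], xyz[:, oxy]
                )
            )
        elif metric == "dfg":
            idx = _m.dfg_atom_indices(topo, label, anchors)
            per_protomer_eval.append(
                lambda xyz, idx=idx: _m.torsion_angle(
                    xyz[:, idx[0]], xyz[:, idx[1]], xyz[:, idx[2]], xyz[:, idx[3]]
                )
            )
        else:  # lig501
            if ligand is None:
                raise ValueError("metric 'lig501' requires a ligand")
            lig_id = ligand if ligand in topo.ligands else \
                topo.ligand_for_protomer(label, name=ligand.split(":")[0])
            if lig_id is None:
                raise ValueError(f"no copy of ligand {ligand!r} in protomer {label!r}")
            typing = _fp.type_ligand_atoms(topo, lig_id)
            lig_idx_all = topo.ligand_indices(lig_id)
            names = topo.atoms.atom_name[lig_idx_all]
            donors = lig_idx_all[np.isin(names, list(typing.donor_atoms))]
            if donors.size == 0:
                raise ValueError(f"ligand {lig_id!r} has no donor atoms")
            oxy = topo.residue_atom_indices(
                label, anchors.alpha_c_glutamate, atom_names=["OE1", "OE2"]
            )
            per_protomer_eval.append(
                lambda xyz, donors=donors, oxy=oxy: _m.min_pair_distance(
                    xyz[:, donors], xyz[:, oxy]
                )
            )

    values = []
    for r in range(ensemble.n_replicas):
        xyz = ensemble.analysis_coords(r)
        cols = [f(xyz) for f in per_protomer_eval]
        values.append(np.stack(cols, axis=1))
    return MetricTimeSeries(
        ensemble_id=topo.source or "ensemble",
        metric_name=metric,
        units=METRICS[metric][1],
        protomer_labels=tuple(labels),
        values=values,
    )


@dataclass(frozen=True)
class DistributionSummary:
    """A 50-bin (by default) probability distribution of one metric."""

    bin_edges: np.ndarray    # (n_bins + 1,), strictly increasing
    probabilities: np.ndarray  # (n_bins,), sums to 1
    n_samples: int
    pooled_protomers: bool

    def __post_init__(self):
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if abs(self.probabilities.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1 within 1e-12")
        if np.any(self.probabilities < 0):
            raise ValueError("probabilities must be non-negative")

    def peak_position(self) -> float:
        """Midpoint of the highest-probability bin (ties → lower bin)."""
        i = int(np.argmax(self.probabilities))
        return float(0.5 * (self.bin_edges[i] + self.bin_edges[i + 1]))


def _histogram_range(data: np.ndarray, range_=None) -> tuple[float, float]:
    if range_ is not None:
        lo, hi = float(range_[0]), float(range_[1])
    else:
        lo, hi = float(data.min()), float(data.max())
        pad = 0.01 * (hi - lo)
        lo, hi = lo - pad, hi + pad
    if hi <= lo:  # all values identical (or degenerate request)
        lo, hi = lo - 0.5, hi + 0.5
    return lo, hi


def distribution(
    series: MetricTimeSeries,
    n_bins: int = 50,
    pool_protomers: bool = True,
    range=None,
):
    """Normalized histogram of a metric time series.

    Replicas are always pooled before binning.  With ``pool_protomers=True``
    (the default dimer convention) both protomers contribute to a single
    distribution; otherwise a dict of per-protomer distributions is returned
    (the protomer-resolved mode used for asymmetric, e.g. singly-ligated,
    dimers).  The default histogram range is the pooled data range padded by
    1%; pass ``range`` for cross-ensemble comparability.
    """
    data = series.pooled(pool_protomers=True)
    if data.size == 0:
        raise EmptyInputError("cannot histogram an empty series")
    if not pool_protomers:
        shared = _histogram_range(data, range)
        return {
            label: distribution(
                series.protomer_series(label), n_bins, True, shared
            )
            for label in series.protomer_labels
        }
    lo, hi = _histogram_range(data, range)
    counts, edges = np.histogram(data, bins=n_bins, range=(lo, hi))
    n_in = int(counts.sum())
    if n_in == 0:
        raise EmptyInputError("no samples fall inside the requested range")
    return DistributionSummary(
        bin_edges=edges,
        probabilities=counts / n_in,
        n_samples=n_in,
        pooled_protomers=True,
    )


@dataclass(frozen=True)
class ProbabilityEstimate:
    """A state probability: per-replica fractions, their mean and SD."""

    per_replica: tuple[float, ...]
    mean: float
    sd: float

    def __post_init__(self):
        if not all(0 <= p <= 1 for p in self.per_replica):
            raise ValueError("per-replica fractions must lie in [0, 1]")


#: named frame predicates usable with :func:`state_probability`
def _predicates(thresholds: Thresholds):
    return {
        "salt_bridge": lambda v: v <= thresholds.salt_bridge_cutoff,
        "alpha_c_in": lambda v: v < thresholds.alpha_c_in_cutoff,
        "alpha_c_in_sidechain": lambda v: v <= thresholds.alpha_c_in_sidechain_cutoff,
        "dfg_in": lambda v: v < thresholds.dfg_in_cutoff,
        "glu501_hbond": lambda v: v <= thresholds.hbond_cutoff,
    }


def state_probability(
    series: MetricTimeSeries,
    predicate,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> ProbabilityEstimate:
    """Fraction of frames satisfying a state predicate, replica-resolved.

    ``predicate`` is either a vectorized callable (values → booleans) or one
    of the named rules: "salt_bridge" (≤ 4.0 Å), "alpha_c_in" (< 19.6 Å),
    "alpha_c_in_sidechain" (≤ 4.5 Å), "dfg_in" (< 140°), "glu501_hbond"
    (≤ 3.5 Å).  Protomers are pooled within each replica.  The mean is the
    unweighted average of the per-replica fractions; the SD uses the n−1
    denominator and is reported as 0 (with a warning) for a single replica.
    """
    if isinstance(predicate, str):
        table = _predicates(thresholds)
        if predicate not in table:
            raise ValueError(
                f"unknown predicate {predicate!r}; choose from {sorted(table)}"
            )
        predicate = table[predicate]
    fracs = []
    for v in series.values:
        flags = np.asarray(predicate(v), dtype=bool)
        fracs.append(float(flags.mean()))
    if len(fracs) == 1:
        warnings.warn(
            "single replica: across-replica SD reported as 0", stacklevel=2
        )
        sd = 0.0
    else:
        sd = float(np.std(fracs, ddof=1))
    return ProbabilityEstimate(
        per_replica=tuple(fracs), mean=float(np.mean(fracs)), sd=sd
    )


@dataclass(frozen=True)
class Density2D:
    """Normalized joint histogram of two aligned metric series."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    densities: np.ndarray  # (n_x_bins, n_y_bins), total mass 1
    x_name: str
    y_name: str

    def __post_init__(self):
        if abs(self.densities.sum() - 1.0) > 1e-12:
            raise ValueError("total mass must be 1 within 1e-12")
        if np.any(self.densities < 0):
            raise ValueError("densities must be non-negative")


def density2d(
    series_x: MetricTimeSeries,
    series_y: MetricTimeSeries,
    bins: int | tuple[int, int] = 50,
    range=None,
) -> Density2D:
    """Joint normalized histogram of two frame-aligned series.

    The canonical axes are the ligand–Glu501 minimum distance (x) against the
    αC position (y), the plane in which the h-bond/helix-position coupling is
    read off.  Series must share replica structure frame by frame.
    """
    if series_x.n_replicas != series_y.n_replicas or any(
        vx.shape != vy.shape for vx, vy in zip(series_x.values, series_y.values)
    ):
        raise AlignmentError(
            "series are not frame-aligned: "
            f"{[v.shape for v in series_x.values]} vs "
            f"{[v.shape for v in series_y.values]}"
        )
    x = series_x.pooled()
    y = series_y.pooled()
    if x.size == 0:
        raise EmptyInputError("cannot histogram empty series")
    if range is None:
        range = (_histogram_range(x), _histogram_range(y))
    counts, x_edges, y_edges = np.histogram2d(x, y, bins=bins, range=range)
    total = counts.sum()
    if total == 0:
        raise EmptyInputError("no samples fall inside the requested range")
    return Density2D(
        x_edges=x_edges,
        y_edges=y_edges,
        densities=counts / total,
        x_name=series_x.metric_name,
        y_name=series_y.metric_name,
    )
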