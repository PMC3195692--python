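"""Axial orientation statistics for cell-angle samples.

Cell orientation is measured as the angle theta of the long axis relative
to the stretch axis, always reported between 0 and 90 degrees (the
orientation is axial: a cell at 110 degrees is the same as one at 70).
Samples are summarized the way the source experiments were:

* a 19-group histogram -- a singleton bin at exactly 0 degrees followed
  by eighteen 5-degree-wide groups 1-5, 6-10, ..., 86-90, with
  frequencies expressed as percent of the total;
* arithmetic mean and SD of the folded angles (not circular statistics;
  a uniform sample on [0, 90] gives mean ~45, SD ~26, consistent with the
  unstretched reference of mean 43 / SD 24);
* replicate summaries that separate variation of the average angle across
  independent experiments from the within-sample heterogeneity averaged
  over experiments.

Angles are assumed recorded at integer-degree precision (protractor-style
measurement); continuous angles are rounded half-up before binning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AngleSample",
    "OrientationHistogram",
    "ReplicateSummary",
    "fold_axial",
    "bin_orientations",
    "orientation_summary",
    "replicate_summary",
    "read_angles_csv",
    "write_angles_csv",
    "write_histogram_csv",
    "write_summary_csv",
]

N_BINS = 19


def fold_axial(angle):
    """Fold any angle to the axial range [0, 90] degrees.

    Reduces modulo 180, then reflects (90, 180) onto (0, 90).  Idempotent.
    """
    a = np.mod(np.asarray(angle, dtype=float), 180.0)
    out = np.where(a > 90.0, 180.0 - a, a)
    return out if out.ndim else float(out)


@dataclass
class AngleSample:
    """A sample of folded cell orientations with a condition/time label."""

    angles: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 1:
            raise ValueError("angles must be one-dimensional")
        if self.angles.size and (self.angles.min() < 0.0 or self.angles.max() > 90.0):
            raise ValueError("angles must lie in [0, 90]; apply fold_axial first")

    @property
    def n(self) -> int:
        return self.angles.size


@dataclass
class OrientationHistogram:
    """19-group orientation histogram with frequencies in percent."""

    labels: list
    frequencies: np.ndarray  # percent, sums to 100
    n: int = 0

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if len(self.labels) != N_BINS or self.frequencies.size != N_BINS:
            raise ValueError(f"expected exactly {N_BINS} bins")


def _round_int_degrees(angles: np.ndarray) -> np.ndarray:
    # half-up rounding, as a protractor reading would be recorded
    return np.floor(angles + 0.5).astype(int)


def bin_orientations(sample: AngleSample) -> OrientationHistogram:
    """Histogram a folded angle sample into the 19-group 5-degree scheme.

    Groups: {0}, 1-5, 6-10, ..., 86-90 (integer-degree semantics; angles
    are rounded to whole degrees first).  Frequencies are percent of the
    total and sum to 100.
    """
    if sample.n == 0:
        raise ValueError("cannot histogram an empty sample")
    ints = _round_int_degrees(sample.angles)
    counts = np.zeros(N_BINS, dtype=float)
    counts[0] = np.sum(ints == 0)
    for k in range(1, N_BINS):
        lo, hi = 5 * (k - 1) + 1, 5 * k
        counts[k] = np.sum((ints >= lo) & (ints <= hi))
    labels = ["0"] + [f"{5 * (k - 1) + 1}-{5 * k}" for k in range(1, N_BINS)]
    return OrientationHistogram(labels, 100.0 * counts / sample.n, n=sample.n)


def orientation_summary(sample: AngleSample) -> tuple[float, float]:
    """Arithmetic mean and SD (ddof=1) of the folded angles, in degrees."""
    if sample.n < 2:
        raise ValueError("need at least 2 angles for a mean/SD summary")
    return float(sample.angles.mean()), float(sample.angles.std(ddof=1))


@dataclass
class ReplicateSummary:
    """Across-replicate summary of per-sample orientation statistics.

    ``mean_of_means`` +/- ``sd_across_replicates`` describes how the
    average angle varies between independent experiments;
    ``mean_within_sd`` is the within-sample heterogeneity (SD of angles
    inside one experiment) averaged over experiments.
    """

    mean_of_means: float
    sd_across_replicates: float
    mean_within_sd: float
    n_replicates: int
    replicate_means: np.ndarray = field(default_factory=lambda: np.array([]))
    replicate_sds: np.ndarray = field(default_factory=lambda: np.array([]))


def replicate_summary(samples) -> ReplicateSummary:
    """Summarize a list of replicate angle samples (one per experiment)."""
    if len(samples) < 2:
        raise ValueError("need at least 2 replicate samples")
    means = np.array([s.angles.mean() for s in samples])
    sds = np.array([s.angles.std(ddof=1) for s in samples])
    return ReplicateSummary(
        mean_of_means=float(means.mean()),
        sd_across_replicates=float(means.std(ddof=1)),
        mean_within_sd=float(sds.mean()),
        n_replicates=len(samples),
        replicate_means=means,
        replicate_sds=sds,
    )


# ---------------------------------------------------------------------------
# CSV dialect: one angle per row, degrees, with a label column.

def write_angles_csv(samples, path) -> None:
    frames = [
        pd.DataFrame({"label": s.label, "angle_deg": s.angles}) for s in np.atleast_1d(samples)
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_angles_csv(path) -> list:
    df = pd.read_csv(path)
    if "angle_deg" not in df.columns:
        raise ValueError("angle CSV must have an 'angle_deg' column")
    if "label" not in df.columns:
        return [AngleSample(df["angle_deg"].to_numpy(), "")]
    return [
        AngleSample(g["angle_deg"].to_numpy(), str(label))
        for label, g in df.groupby("label", sort=False)
    ]


def write_histogram_csv(hist: OrientationHistogram, path) -> None:
    pd.DataFrame({"bin_label": hist.labels, "percent": hist.frequencies}).to_csv(
        path, index=False)


def write_summary_csv(samples, path) -> None:
    rows = []
    for s in samples:
        mean, sd = orientation_summary(s)
        rows.append({"label": s.label, "n": s.n, "mean_deg": mean, "sd_deg": sd})
    pd.DataFrame(rows).to_csv(path, index=False)
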