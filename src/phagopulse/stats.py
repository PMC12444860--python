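"""Cohort-level summary statistics.

The primary analysis unit is the neutrophil: the headline quantity is the
percentage of pulsing phagosomes *per phagocytic neutrophil* (mean ± s.d.
over neutrophils), alongside the share of neutrophils with at least one
pulsing phagosome.  Pooled per-phagosome rates are also emitted, clearly
labelled, since both weightings are defensible.  Further operations cover
the bacterial-burden correlation (Spearman with midrank ties), relative
intensity change inside phagosome masks (pH / ROS reporters), fluid-phase
dye-positive classification, the peri-bacterial ROS shell ratio, standard
group comparisons, and exact binomial summaries of categorical event
tallies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage, stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, ShapeError, StateError
from .segmentation import LabelVolume

__all__ = [
    "NeutrophilRecord",
    "EventTally",
    "MaskIntensitySeries",
    "pulsing_summary",
    "burden_correlation",
    "SpearmanResult",
    "relative_change",
    "dye_positive_fraction",
    "dcf_shell_ratio",
    "compare_groups",
    "tally_statistics",
    "clopper_pearson",
    "load_event_tally",
]


@dataclass
class NeutrophilRecord:
    """Per-neutrophil tallies derived from the calls table."""

    neutrophil_id: int
    n_bacteria: int
    phagosome_ids: list[int]
    n_pulsing: int

    def __post_init__(self):
        if self.n_pulsing > len(self.phagosome_ids):
            raise ConfigurationError(
                f"neutrophil {self.neutrophil_id}: pulsing count {self.n_pulsing} "
                f"exceeds phagosome count {len(self.phagosome_ids)}")

    @property
    def n_phagosomes(self) -> int:
        return len(self.phagosome_ids)

    @property
    def fraction_pulsing_pct(self) -> float:
        return 100.0 * self.n_pulsing / self.n_phagosomes


def pulsing_summary(
    records: list[NeutrophilRecord],
    latencies_min: list[float] | None = None,
    pulse_counts: list[int] | None = None,
) -> dict:
    """Cohort pulsing statistics, computed over neutrophils.

    Neutrophils with zero phagosomes are excluded (and counted in the
    report).  ``latencies_min`` / ``pulse_counts`` are the per-pulsing-
    phagosome first-pulse latencies and pulse counts, if available.
    """
    usable = [r for r in records if r.n_phagosomes > 0]
    excluded = len(records) - len(usable)
    if not usable:
        raise ConfigurationError("no neutrophil with at least one phagosome")
    fracs = np.array([r.fraction_pulsing_pct for r in usable])
    any_pulsing = np.array([r.n_pulsing > 0 for r in usable])
    total_ph = sum(r.n_phagosomes for r in usable)
    total_pulsing = sum(r.n_pulsing for r in usable)
    out = {
        "n_neutrophils": len(usable),
        "n_neutrophils_excluded_zero_phagosomes": excluded,
        "n_phagosomes": total_ph,
        "pct_pulsing_per_neutrophil_mean": float(fracs.mean()),
        "pct_pulsing_per_neutrophil_sd": float(fracs.std(ddof=1)) if len(fracs) > 1 else 0.0,
        "pct_neutrophils_with_pulsing": 100.0 * float(any_pulsing.mean()),
        "pct_pulsing_pooled_phagosomes": 100.0 * total_pulsing / total_ph,
    }
    if latencies_min is not None:
        lat = np.asarray([v for v in latencies_min if v is not None], float)
        out["n_latencies"] = int(lat.size)
        out["latency_min_mean"] = float(lat.mean()) if lat.size else None
        out["latency_min_sd"] = float(lat.std(ddof=1)) if lat.size > 1 else 0.0
    if pulse_counts is not None:
        pc = np.asarray(pulse_counts, int)
        vals, counts = np.unique(pc, return_counts=True) if pc.size else ([], [])
        out["pulse_count_distribution"] = {int(v): int(c) for v, c in zip(vals, counts)}
        out["pulse_count_max"] = int(pc.max()) if pc.size else 0
    return out


class SpearmanResult(NamedTuple):
    rho: float
    pvalue: float
    valid: bool


def burden_correlation(records: list[NeutrophilRecord]) -> SpearmanResult:
    """Spearman rank correlation (midrank ties, two-sided p) between the
    number of bacteria and the number of pulsing phagosomes per neutrophil."""
    if len(records) < 3:
        raise ConfigurationError("burden correlation requires at least 3 neutrophils")
    x = np.array([r.n_bacteria for r in records], float)
    y = np.array([r.n_pulsing for r in records], float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return SpearmanResult(np.nan, np.nan, False)
    rho, p = sps.spearmanr(x, y)
    return SpearmanResult(float(rho), float(p), True)


@dataclass
class MaskIntensitySeries:
    """Mean intensity within one object's mask over labelled timepoints."""

    object_id: int
    channel: str
    timepoints_min: np.ndarray
    values: np.ndarray
    group: str = ""               # e.g. "pulsing" / "non-pulsing"

    def __post_init__(self):
        self.timepoints_min = np.asarray(self.timepoints_min, float)
        self.values = np.asarray(self.values, float)
        if len(self.timepoints_min) != len(self.values):
            raise ConfigurationError("timepoints and values differ in length")
        if np.any(np.diff(self.timepoints_min) < 0):
            raise ConfigurationError("timepoints must be ordered")
        if np.any(self.values < 0):
            raise ConfigurationError("intensities must be >= 0")


def relative_change(
    series_list: list[MaskIntensitySeries],
    baseline_min: float,
) -> tuple[pd.DataFrame, pd.DataFrame, list[int]]:
    """Per-object intensity relative to its value at the baseline timepoint.

    Returns (per-object table, per-group mean ± s.d. with n per timepoint,
    ids excluded for a zero baseline).
    """
    rows = []
    excluded = []
    for s in series_list:
        match = np.flatnonzero(np.isclose(s.timepoints_min, baseline_min))
        if len(match) == 0:
            raise ConfigurationError(
                f"object {s.object_id}: baseline timepoint {baseline_min} absent")
        base = s.values[match[0]]
        if base == 0:
            excluded.append(s.object_id)
            continue
        for t, v in zip(s.timepoints_min, s.values):
            rows.append({"object_id": s.object_id, "group": s.group, "channel": s.channel,
                         "timepoint_min": t, "relative_change": v / base})
    per_object = pd.DataFrame(rows, columns=["object_id", "group", "channel",
                                             "timepoint_min", "relative_change"])
    if len(per_object):
        grp = (per_object.groupby(["group", "timepoint_min"])["relative_change"]
               .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0, n="count")
               .reset_index())
    else:
        grp = pd.DataFrame(columns=["group", "timepoint_min", "mean", "sd", "n"])
    return per_object, grp, excluded


def dye_positive_fraction(
    intensities: np.ndarray,
    background_mean: float | None = None,
    background_sd: float | None = None,
    k: float = 3.0,
    fixed_threshold: float | None = None,
) -> tuple[float, np.ndarray, float]:
    """Classify phagosomes as dye-positive by a threshold rule.

    Threshold is ``background_mean + k * background_sd`` (default k = 3) or
    an explicit ``fixed_threshold``.  Returns (percent positive, boolean
    labels, threshold used).
    """
    intensities = np.asarray(intensities, float)
    if intensities.size == 0:
        raise StateError("no post-dye intensities supplied")
    if fixed_threshold is not None:
        thr = float(fixed_threshold)
    else:
        if background_mean is None or background_sd is None:
            raise ConfigurationError(
                "need background_mean and background_sd (or a fixed_threshold)")
        thr = float(background_mean + k * background_sd)
    labels = intensities > thr
    return 100.0 * float(labels.mean()), labels, thr


def dcf_shell_ratio(
    frame: np.ndarray,
    prey: LabelVolume,
    reference_mean: float,
    shell_radius_um: float = 0.5,
) -> pd.DataFrame:
    """Peri-bacterial shell intensity over a reference phagocyte signal.

    For each labelled bacterium, the shell is the set of voxels within
    ``shell_radius_um`` (Euclidean distance in µm, anisotropy honoured) of
    the bacterium mask, excluding the mask itself; the ratio is the shell's
    mean intensity in ``frame`` divided by ``reference_mean``.  Bacteria
    whose shell is empty after clipping are flagged.
    """
    if shell_radius_um <= 0:
        raise ConfigurationError("shell radius must be > 0")
    if reference_mean <= 0:
        raise ConfigurationError("reference mean must be > 0 (non-empty reference set)")
    frame = np.asarray(frame)
    if frame.shape != prey.labels.shape:
        raise ShapeError(f"frame {frame.shape} vs labels {prey.labels.shape}")
    sx, sy, sz = prey.voxel_size
    sampling = (sz, sy, sx)  # labels are (Z, Y, X)
    rows = []
    for lab in range(1, prey.n_labels + 1):
        mask = prey.labels == lab
        dist = ndimage.distance_transform_edt(~mask, sampling=sampling)
        shell = (dist > 0) & (dist <= shell_radius_um)
        if not shell.any():
            rows.append({"label": lab, "shell_mean": np.nan, "ratio": np.nan,
                         "n_shell_voxels": 0, "empty_shell": True})
            continue
        m = float(frame[shell].mean())
        rows.append({"label": lab, "shell_mean": m, "ratio": m / reference_mean,
                     "n_shell_voxels": int(shell.sum()), "empty_shell": False})
    return pd.DataFrame(rows, columns=["label", "shell_mean", "ratio",
                                       "n_shell_voxels", "empty_shell"])


# --------------------------------------------------------------------------
# group comparisons
# --------------------------------------------------------------------------

def _dunn_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's pairwise z-tests after Kruskal-Wallis, Holm-adjusted."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    ranks = sps.rankdata(pooled)
    N = len(pooled)
    # tie correction sum(t^3 - t)
    _, counts = np.unique(pooled, return_counts=True)
    tie = np.sum(counts ** 3 - counts)
    offsets = np.cumsum([0] + [len(groups[g]) for g in names])
    mean_rank = {g: ranks[offsets[i]:offsets[i + 1]].mean() for i, g in enumerate(names)}
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            na, nb = len(groups[a]), len(groups[b])
            var = (N * (N + 1) / 12.0 - tie / (12.0 * (N - 1))) * (1.0 / na + 1.0 / nb)
            z = (mean_rank[a] - mean_rank[b]) / np.sqrt(var)
            p = 2 * sps.norm.sf(abs(z))
            rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_holm"] = multipletests(df["p_raw"], method="holm")[1]
    return df


def compare_groups(values_by_group: dict[str, np.ndarray], design: str = "kruskal"):
    """Standard between-group tests (reporting plumbing, not bespoke science).

    design = "kruskal": Kruskal-Wallis H plus Dunn pairwise comparisons with
    Holm adjustment; "mannwhitney" / "ttest": the respective two-sample
    test (exactly two groups).  Returns a dict with the overall statistic,
    p-value, per-group n, and any post-hoc table.  Groups with n < 2 are
    flagged for the t-test.
    """
    groups = {k: np.asarray(v, float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ConfigurationError("need at least two groups")
    ns = {k: len(v) for k, v in groups.items()}
    out = {"design": design, "n_per_group": ns, "flags": []}
    vals = list(groups.values())
    if design == "kruskal":
        H, p = sps.kruskal(*vals)
        out.update(statistic=float(H), pvalue=float(p))
        out["posthoc"] = _dunn_posthoc(groups)
    elif design == "mannwhitney":
        if len(groups) != 2:
            raise ConfigurationError("Mann-Whitney needs exactly two groups")
        U, p = sps.mannwhitneyu(vals[0], vals[1], alternative="two-sided")
        out.update(statistic=float(U), pvalue=float(p))
    elif design == "ttest":
        if len(groups) != 2:
            raise ConfigurationError("t-test needs exactly two groups")
        if any(n < 2 for n in ns.values()):
            out["flags"].append("group with n < 2: t-test unreliable")
        t, p = sps.ttest_ind(vals[0], vals[1], equal_var=False)
        out.update(statistic=float(t), pvalue=float(p))
    else:
        raise ConfigurationError(f"unknown design {design!r}")
    return out


# --------------------------------------------------------------------------
# categorical event tallies
# --------------------------------------------------------------------------

@dataclass
class EventTally:
    """Numerator/denominator counts of categorical outcomes.

    ``entries`` maps an event name to (numerator, denominator, decimals)
    where decimals is the printing precision of the percentage.
    """

    entries: dict[str, tuple[int, int, int]]

    def __post_init__(self):
        for name, (num, den, dec) in self.entries.items():
            if den <= 0:
                raise ConfigurationError(f"{name}: zero/negative denominator")
            if not 0 <= num <= den:
                raise ConfigurationError(f"{name}: numerator {num} outside [0, {den}]")


def clopper_pearson(num: int, den: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval for num/den."""
    if den <= 0:
        raise ConfigurationError("zero denominator")
    lo = 0.0 if num == 0 else float(sps.beta.ppf(alpha / 2, num, den - num + 1))
    hi = 1.0 if num == den else float(sps.beta.ppf(1 - alpha / 2, num + 1, den - num))
    return lo, hi


def tally_statistics(tally: EventTally) -> pd.DataFrame:
    """Percentages (at their printing precision) with exact 95% binomial CIs."""
    rows = []
    for name, (num, den, dec) in tally.entries.items():
        pct = 100.0 * num / den
        lo, hi = clopper_pearson(num, den)
        rows.append({
            "event": name, "numerator": num, "denominator": den,
            "percent": round(pct, dec) if dec > 0 else round(pct),
            "percent_exact": pct,
            "ci95_low_pct": 100.0 * lo, "ci95_high_pct": 100.0 * hi,
        })
    return pd.DataFrame(rows, columns=["event", "numerator", "denominator", "percent",
                                       "percent_exact", "ci95_low_pct", "ci95_high_pct"])


def load_event_tally(path=None) -> EventTally:
    """Load an event tally from YAML (default: the packaged cohort fixture)."""
    if path is None:
        from importlib.resources import files
        path = files("phagopulse.data").joinpath("event_tallies.yaml")
        text = path.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    entries = {name: (int(e["numerator"]), int(e["denominator"]),
                      int(e.get("decimals", 1)))
               for name, e in raw.items()}
    return EventTally(entries)
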