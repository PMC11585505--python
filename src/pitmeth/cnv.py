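"""Copy-number analysis from methylation-array total intensities.

Per-sample log2 intensity ratios against a reference panel are binned along
the genome, segmented by recursive binary splitting with a permutation stop
rule, and summarized as chromosome-arm states (gain / loss / balanced, at a
50%-of-arm cutoff). Group-level cumulative profiles flag arms altered in
more than 50% of specimens; per-sample altered-arm burdens, Jaccard-distance
clustering of the factorized gain/loss matrix, and a chromothripsis-style
oscillation flag complete the stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .cluster import Dendrogram
from .preprocess import validate_sample_sheet

logger = logging.getLogger("pitmeth")

#: default segment-mean thresholds (log2 units) for gain / loss state
GAIN_CUT = 0.1
LOSS_CUT = -0.1


@dataclass
class CNVSegment:
    """A constant-copy-number stretch of one sample's genome.

    Coordinates are 0-based half-open basepairs.
    """

    sample: str
    chrom: str
    start: int
    end: int
    mean: float
    n_bins: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("segment start must be < end")


# ---------------------------------------------------------------------------
# log ratios and binning
# ---------------------------------------------------------------------------

def compute_log_ratios(
    intensity: pd.DataFrame,
    reference_samples,
) -> pd.DataFrame:
    """log2(sample / reference median) per probe.

    The per-probe reference level is the median intensity across the
    reference panel (>= 3 samples); probes with zero reference median are
    dropped with a warning.
    """
    reference_samples = list(reference_samples)
    if len(reference_samples) < 3:
        raise ValueError("need at least 3 reference samples")
    ref = intensity[reference_samples].median(axis=1)
    zero = ref <= 0
    if zero.any():
        logger.warning("%d probes have zero reference median; dropped", int(zero.sum()))
        intensity = intensity.loc[~zero]
        ref = ref[~zero]
    x = intensity.to_numpy(float)
    with np.errstate(divide="ignore"):
        lr = np.log2(np.maximum(x, 1e-12) / ref.to_numpy()[:, None])
    return pd.DataFrame(lr, index=intensity.index, columns=intensity.columns)


def bin_signal(
    log_ratios: pd.DataFrame,
    manifest: pd.DataFrame,
    bin_size: int = 500_000,
) -> pd.DataFrame:
    """Median log-ratio over fixed non-overlapping genomic bins.

    Returns a DataFrame indexed by (chrom, start, end) — 0-based half-open —
    with one column per sample; bins containing no probe are absent (treated
    as missing downstream).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    ann = manifest.loc[log_ratios.index]
    start0 = (ann["pos"].to_numpy(np.int64) - 1) // bin_size * bin_size
    keys = pd.DataFrame(
        {"chrom": ann["chrom"].to_numpy(), "start": start0, "end": start0 + bin_size},
        index=log_ratios.index,
    )
    grouped = log_ratios.groupby(
        [keys["chrom"], keys["start"], keys["end"]], sort=True
    ).median()
    grouped.index.names = ["chrom", "start", "end"]
    return grouped


# ---------------------------------------------------------------------------
# segmentation (recursive binary splitting, permutation stop rule)
# ---------------------------------------------------------------------------

_MAX_CANDIDATES = 300  # boundary grid cap; exact below, strided above


def _arc_stat(y: np.ndarray, min_bins: int) -> tuple[int, int, float]:
    """Best arc [i, j) of y by the two-sample t of arc vs rest.

    Circular binary segmentation statistic: the candidate change is an
    interior arc of at least ``min_bins`` bins whose complement also has at
    least ``min_bins`` bins; a plain edge split is the special case i = 0 or
    j = n. For chromosomes longer than ``_MAX_CANDIDATES`` bins the boundary
    grid is strided (recursion restores resolution inside accepted pieces).
    Returns (i, j, |t|); |t| may be inf for a noiseless step.
    """
    n = y.size
    cs = np.concatenate([[0.0], np.cumsum(y)])
    cq = np.concatenate([[0.0], np.cumsum(y * y)])
    if n + 1 > _MAX_CANDIDATES:
        pos = np.unique(np.round(np.linspace(0, n, _MAX_CANDIDATES)).astype(int))
    else:
        pos = np.arange(n + 1)
    cs, cq = cs[pos], cq[pos]
    length = pos[None, :] - pos[:, None]      # j - i
    valid = (length >= min_bins) & (length <= n - min_bins)
    s_in = cs[None, :] - cs[:, None]
    q_in = cq[None, :] - cq[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        n1 = length.astype(float)
        n2 = n - n1
        m1 = s_in / n1
        m2 = (cs[-1] - s_in) / n2
        ss = (q_in - n1 * m1 ** 2) + ((cq[-1] - q_in) - n2 * m2 ** 2)
        pooled = np.maximum(ss / max(n - 2, 1), 0.0)
        t = np.abs(m1 - m2) / np.sqrt(pooled * (1 / n1 + 1 / n2))
    t = np.where(np.isnan(t), np.where(np.abs(m1 - m2) > 0, np.inf, 0.0), t)
    t = np.where(valid, t, -np.inf)
    flat = int(np.argmax(t))
    bi, bj = divmod(flat, pos.size)
    return int(pos[bi]), int(pos[bj]), float(t[bi, bj])


def _segment_one(
    y: np.ndarray,
    min_bins: int,
    alpha: float,
    n_perm: int,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Recursive circular binary segmentation; returns index ranges."""
    n = y.size
    if n < 2 * min_bins:
        return [(0, n)]
    i, j, t_obs = _arc_stat(y, min_bins)
    if t_obs <= 0:
        return [(0, n)]
    # sequential permutation test with early stop: once `exceed` reaches
    # ceil(alpha * n_perm) the decision p >= alpha is settled
    stop_at = int(np.ceil(alpha * n_perm))
    exceed = 0
    for _ in range(n_perm):
        yp = rng.permutation(y)
        _, _, t_p = _arc_stat(yp, min_bins)
        if t_p >= t_obs:
            exceed += 1
            if exceed >= stop_at:
                return [(0, n)]
    if exceed / n_perm >= alpha:
        return [(0, n)]
    pieces = [(0, i), (i, j), (j, n)]
    out: list[tuple[int, int]] = []
    for a, b in pieces:
        if b - a == 0:
            continue
        sub = _segment_one(y[a:b], min_bins, alpha, n_perm, rng)
        out.extend((p + a, q + a) for p, q in sub)
    return out


def segment_bins(
    binned: pd.DataFrame,
    min_bins: int = 5,
    alpha: float = 0.01,
    n_perm: int = 200,
    seed: int = 0,
) -> list[CNVSegment]:
    """Segment each sample's binned log-ratio profile per chromosome.

    Circular binary segmentation: the candidate change is the arc whose
    two-sample t statistic against the rest of the chromosome is maximal
    (an edge split is the degenerate arc), accepted when its permutation
    p-value is below ``alpha`` (``n_perm`` seeded shuffles); recursion stops
    when no acceptance or a piece would drop below ``min_bins`` bins.
    Missing bins are excluded.
    """
    if min_bins < 2:
        raise ValueError("min_bins must be at least 2")
    rng = np.random.default_rng(seed)
    segments: list[CNVSegment] = []
    chroms = binned.index.get_level_values("chrom")
    for chrom in chroms.unique():
        sub = binned.xs(chrom, level="chrom", drop_level=False)
        starts = sub.index.get_level_values("start").to_numpy()
        ends = sub.index.get_level_values("end").to_numpy()
        for sample in binned.columns:
            y = sub[sample].to_numpy(float)
            ok = np.isfinite(y)
            yv, sv, ev = y[ok], starts[ok], ends[ok]
            if yv.size == 0:
                continue
            for a, b in _segment_one(yv, min_bins, alpha, n_perm, rng):
                segments.append(
                    CNVSegment(
                        sample=sample,
                        chrom=str(chrom),
                        start=int(sv[a]),
                        end=int(ev[b - 1]),
                        mean=float(yv[a:b].mean()),
                        n_bins=int(b - a),
                    )
                )
    return segments


# ---------------------------------------------------------------------------
# arm calls and group summaries
# ---------------------------------------------------------------------------

def call_arm_states(
    segments: list[CNVSegment],
    arms: pd.DataFrame,
    gain_cut: float = GAIN_CUT,
    loss_cut: float = LOSS_CUT,
    arm_fraction: float = 0.5,
    samples=None,
) -> pd.DataFrame:
    """Score every (sample, arm) as gain / loss / balanced.

    A segment is gained if its mean >= gain_cut and lost if <= loss_cut;
    per arm the basepair fraction covered by gained (resp. lost) segments
    decides the state at the ``arm_fraction`` cutoff. An exact tie between
    the two fractions at the cutoff is resolved toward the state with the
    larger total |mean| x length, and logged.
    """
    if not (gain_cut > 0 > loss_cut):
        raise ValueError("need gain_cut > 0 > loss_cut")
    if samples is None:
        samples = sorted({s.sample for s in segments})
    by_sample: dict[str, list[CNVSegment]] = {s: [] for s in samples}
    for seg in segments:
        by_sample.setdefault(seg.sample, []).append(seg)

    rows = []
    for sample in samples:
        segs = by_sample.get(sample, [])
        for _, arm_row in arms.iterrows():
            chrom, a_start, a_end, arm = (
                arm_row["chrom"], int(arm_row["start"]), int(arm_row["end"]), arm_row["arm"],
            )
            arm_len = a_end - a_start
            gained = lost = 0
            gain_w = loss_w = 0.0
            covered = 0
            for seg in segs:
                if seg.chrom != chrom:
                    continue
                ov = min(seg.end, a_end) - max(seg.start, a_start)
                if ov <= 0:
                    continue
                covered += ov
                if seg.mean >= gain_cut:
                    gained += ov
                    gain_w += abs(seg.mean) * ov
                elif seg.mean <= loss_cut:
                    lost += ov
                    loss_w += abs(seg.mean) * ov
            if covered == 0:
                logger.warning("arm %s not covered by any segment in %s; balanced", arm, sample)
            gf, lf = gained / arm_len, lost / arm_len
            if gf >= arm_fraction and lf >= arm_fraction:
                state = "gain" if gain_w >= loss_w else "loss"
                logger.info("tie on arm %s in %s resolved to %s", arm, sample, state)
            elif gf >= arm_fraction:
                state = "gain"
            elif lf >= arm_fraction:
                state = "loss"
            else:
                state = "balanced"
            rows.append((sample, arm, state, gf, lf))
    return pd.DataFrame(
        rows, columns=["sample", "arm", "state", "gain_fraction", "loss_fraction"]
    )


def cumulative_profile(
    calls: pd.DataFrame,
    sheet: pd.DataFrame,
    group_field: str = "group",
) -> pd.DataFrame:
    """Percentage of each group's samples with gain / loss per arm.

    An event is flagged frequent when it occurs in strictly more than 50%
    of the group's specimens.
    """
    sheet = validate_sample_sheet(sheet).set_index("sample")
    rows = []
    for group, members in sheet.groupby(group_field).groups.items():
        members = set(members)
        sub = calls[calls["sample"].isin(members)]
        n = len(members)
        if n == 0:
            raise ValueError(f"group {group!r} is empty")
        for arm, arm_calls in sub.groupby("arm"):
            gain_pct = 100.0 * (arm_calls["state"] == "gain").sum() / n
            loss_pct = 100.0 * (arm_calls["state"] == "loss").sum() / n
            rows.append(
                (group, arm, gain_pct, loss_pct, max(gain_pct, loss_pct) > 50.0)
            )
    return pd.DataFrame(
        rows, columns=["group", "arm", "gain_pct", "loss_pct", "frequent"]
    )


def arm_burden_summary(
    calls: pd.DataFrame,
    sheet: pd.DataFrame,
) -> tuple[pd.Series, pd.DataFrame]:
    """Altered-arm count per sample plus per-group median and range."""
    sheet = validate_sample_sheet(sheet).set_index("sample")
    altered = calls[calls["state"] != "balanced"]
    per_sample = altered.groupby("sample").size()
    per_sample = per_sample.reindex(sheet.index, fill_value=0).astype(int)
    per_sample.name = "altered_arms"
    summary = (
        per_sample.groupby(sheet["group"])
        .agg(median="median", min="min", max="max", n="size")
        .reset_index()
    )
    return per_sample, summary


# ---------------------------------------------------------------------------
# Jaccard clustering of the factorized gain/loss matrix
# ---------------------------------------------------------------------------

def factorize_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Binary samples x (arm, state) feature matrix of non-balanced calls."""
    active = calls[calls["state"].isin(["gain", "loss"])].copy()
    samples = sorted(calls["sample"].unique())
    if active.empty:
        return pd.DataFrame(index=pd.Index(samples, name="sample"), dtype=int)
    active["feature"] = active["arm"] + ":" + active["state"]
    mat = (
        active.assign(v=1)
        .pivot_table(index="sample", columns="feature", values="v", fill_value=0)
        .reindex(samples, fill_value=0)
        .astype(int)
    )
    mat.index.name = "sample"
    return mat


def jaccard_cluster(calls: pd.DataFrame) -> tuple[pd.DataFrame, Dendrogram]:
    """Complete-linkage clustering on Jaccard distance of gain/loss features.

    d(i, j) = 1 - |F_i & F_j| / |F_i | F_j| over the samples' active
    (arm, state) feature sets; two samples with no events are at distance 0
    by convention.
    """
    feats = factorize_calls(calls)
    if len(feats) < 2:
        raise ValueError("need at least 2 samples to cluster")
    x = feats.to_numpy(bool) if feats.shape[1] else np.zeros((len(feats), 1), bool)
    inter = (x[:, None, :] & x[None, :, :]).sum(axis=2).astype(float)
    union = (x[:, None, :] | x[None, :, :]).sum(axis=2).astype(float)
    with np.errstate(invalid="ignore"):
        d = 1.0 - np.where(union > 0, inter / union, 1.0)
    np.fill_diagonal(d, 0.0)
    dist = pd.DataFrame(d, index=feats.index, columns=feats.index)
    z = hierarchy.linkage(squareform(d, checks=False), method="complete")
    return dist, Dendrogram(linkage=z, labels=list(feats.index), metric="jaccard")


# ---------------------------------------------------------------------------
# chromothripsis-style oscillation flag
# ---------------------------------------------------------------------------

def chromothripsis_flags(
    segments: list[CNVSegment],
    min_switches: int = 10,
    gain_cut: float = GAIN_CUT,
    loss_cut: float = LOSS_CUT,
) -> pd.DataFrame:
    """Flag sample-chromosomes whose segment states oscillate gain<->loss.

    Balanced segments between a gain and a loss do not reset the count:
    the switch is scored on the flanking non-balanced states. The default
    of 10 switches is an operational screen for chromothripsis-like
    profiles, configurable by the caller.
    """
    if min_switches < 2:
        raise ValueError("min_switches must be at least 2")
    rows = []
    keyed: dict[tuple[str, str], list[CNVSegment]] = {}
    for seg in segments:
        keyed.setdefault((seg.sample, seg.chrom), []).append(seg)
    for (sample, chrom), segs in sorted(keyed.items()):
        segs = sorted(segs, key=lambda s: s.start)
        states = []
        for seg in segs:
            if seg.mean >= gain_cut:
                states.append("gain")
            elif seg.mean <= loss_cut:
                states.append("loss")
        switches = sum(1 for a, b in zip(states, states[1:]) if a != b)
        rows.append((sample, chrom, switches, switches >= min_switches))
    return pd.DataFrame(rows, columns=["sample", "chrom", "switches", "flagged"])


def segments_to_frame(segments: list[CNVSegment]) -> pd.DataFrame:
    """SEG-style table (ID, chrom, loc.start, loc.end, num.mark, seg.mean)."""
    return pd.DataFrame(
        [(s.sample, s.chrom, s.start, s.end, s.n_bins, s.mean) for s in segments],
        columns=["ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"],
    )
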