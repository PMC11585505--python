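"""Synthetic EPIC-like cohort generator with known ground truth.

Emulates the statistical structure of Illumina methylation-array data at desk
scale: three-state (unmethylated / hemimethylated / methylated) beta
distributions that differ by probe design type, planted group-specific
differential methylation, slide-level batch shifts in logit space, and
planted arm-level and whole-chromosome copy-number events (including
chromothripsis-like gain/loss oscillation) expressed through total
intensities via a purity-mixed copy-number ratio.

Every generated cohort comes with a :class:`SyntheticTruth` record so that
downstream recovery can be scored exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .preprocess import BetaMatrix

logger = logging.getLogger("pitmeth")

SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})

#: three-state beta means by probe design type. Type II chemistry compresses
#: the dynamic range toward 0.5 — the distortion BMIQ corrects.
STATE_MEANS = {"I": (0.05, 0.5, 0.95), "II": (0.15, 0.5, 0.85)}
STATE_PROBS = (0.45, 0.10, 0.45)


# ---------------------------------------------------------------------------
# genome and design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome coordinate system with centromeres splitting p and q arms."""

    chromosomes: tuple[str, ...]
    lengths: dict[str, int]
    centromeres: dict[str, int]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome needs at least one chromosome")
        if len(set(self.chromosomes)) != len(self.chromosomes):
            raise ValueError("chromosome names must be unique")
        for c in self.chromosomes:
            if not 0 < self.centromeres[c] < self.lengths[c]:
                raise ValueError(f"centromere of {c} must lie inside the chromosome")

    def arm_table(self) -> pd.DataFrame:
        """Arm definitions as 0-based half-open intervals (BED convention)."""
        rows = []
        for c in self.chromosomes:
            cen, length = self.centromeres[c], self.lengths[c]
            rows.append((c, 0, cen, f"{c}p"))
            rows.append((c, cen, length, f"{c}q"))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "arm"])

    def arm_interval(self, arm: str) -> tuple[str, int, int]:
        """Resolve an arm label ('chr1p') or bare chromosome to an interval."""
        if arm in self.lengths:
            return arm, 0, self.lengths[arm]
        chrom, suffix = arm[:-1], arm[-1]
        if suffix not in "pq" or chrom not in self.lengths:
            raise ValueError(f"unknown arm label {arm!r}")
        cen = self.centromeres[chrom]
        return (chrom, 0, cen) if suffix == "p" else (chrom, cen, self.lengths[chrom])


def mini_genome(n_chrom: int = 4, length: int = 50_000_000,
                centromere_fraction: float = 0.4) -> GenomeSpec:
    """Default desk-scale genome: 4 x 50 Mb chromosomes, centromere at 40%."""
    names = tuple(f"chr{i + 1}" for i in range(n_chrom))
    return GenomeSpec(
        chromosomes=names,
        lengths={c: length for c in names},
        centromeres={c: int(length * centromere_fraction) for c in names},
    )


@dataclass
class ArmEvent:
    """A planted arm-level (or whole-chromosome) copy-number event."""

    group: str
    arm: str            # arm label like 'chr1p', or bare chromosome for whole-chrom
    state: str          # 'gain' (CN 3) or 'loss' (CN 1)
    prevalence: float   # fraction of the group's samples carrying the event


@dataclass
class ChromothripsisEvent:
    """A planted oscillating gain/loss pattern on one chromosome."""

    group: str
    chrom: str
    n_segments: int = 12
    carriers: int = 1


@dataclass
class CohortDesign:
    """Full parameterization of a synthetic cohort.

    Defaults encode the desk-scale analogue of the study conditions: a
    30-versus-12 contrast (20 aggressive + 10 metastatic vs 12 benign),
    100 planted differentially methylated probes at |delta-beta| = 0.3,
    beta dispersion 50, and no batch shift unless requested.
    """

    n_benign: int = 12
    n_apt: int = 20
    n_pc: int = 10
    n_dmp: int = 100
    delta_beta: float = 0.3
    dmp_groups: tuple[str, ...] = ("APT", "PC")
    dispersion: float = 50.0
    batches: tuple[str, ...] = ("S1",)
    batch_shifts: dict = field(default_factory=dict)  # batch -> logit shift
    arm_events: tuple[ArmEvent, ...] = ()
    chromothripsis: tuple[ChromothripsisEvent, ...] = ()
    purity: float = 1.0
    detection_fail_rate: float = 5e-4
    first_surgery_fraction: float = 0.62
    intensity_log2_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0, 1]")
        if self.n_dmp and not 0 < self.delta_beta < 1:
            raise ValueError("delta_beta must be in (0, 1)")
        for ev in self.arm_events:
            if not 0 <= ev.prevalence <= 1:
                raise ValueError("event prevalence must be in [0, 1]")
            if ev.state not in ("gain", "loss"):
                raise ValueError("event state must be 'gain' or 'loss'")

    @property
    def n_samples(self) -> int:
        return self.n_benign + self.n_apt + self.n_pc


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort, for recovery scoring."""

    dmp_probes: dict            # probe -> signed planted delta-beta
    arm_events: dict            # sample -> list of (arm, state)
    batches: dict               # sample -> batch label
    chromothripsis: list        # (sample, chrom) pairs
    groups: dict                # sample -> group label

    def to_dict(self) -> dict:
        return {
            "dmp_probes": self.dmp_probes,
            "arm_events": self.arm_events,
            "batches": self.batches,
            "chromothripsis": [list(t) for t in self.chromothripsis],
            "groups": self.groups,
        }


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def generate_manifest(
    genome: GenomeSpec,
    n_probes: int,
    gene_density: float = 0.7,
    seed: int = 0,
    type1_fraction: float = 0.15,
    snp_fraction: float = 0.02,
    gene_window: int = 100_000,
) -> pd.DataFrame:
    """Random probe manifest: uniform positions, windowed gene symbols.

    Genes are tiled as fixed ``gene_window`` intervals so that several CpGs
    map to the same gene, as on a real array; a ``gene_density`` fraction of
    probes carries a symbol. About ``type1_fraction`` of probes are design
    type I. Deterministic given ``seed``.
    """
    if n_probes < 1:
        raise ValueError("n_probes must be at least 1")
    rng = np.random.default_rng(seed)
    lengths = np.array([genome.lengths[c] for c in genome.chromosomes], float)
    chrom_idx = rng.choice(len(lengths), size=n_probes, p=lengths / lengths.sum())
    pos = (rng.random(n_probes) * lengths[chrom_idx]).astype(np.int64) + 1
    order = np.lexsort((pos, chrom_idx))
    chrom_idx, pos = chrom_idx[order], pos[order]
    chroms = np.array(genome.chromosomes)[chrom_idx]

    window = (pos - 1) // gene_window
    gene_id = {}
    genes = []
    annotated = rng.random(n_probes) < gene_density
    for c, w, ann in zip(chroms, window, annotated):
        if not ann:
            genes.append("")
            continue
        key = (c, int(w))
        if key not in gene_id:
            gene_id[key] = f"GENE{len(gene_id) + 1:05d}"
        genes.append(gene_id[key])

    manifest = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "gene": genes,
            "design_type": np.where(rng.random(n_probes) < type1_fraction, "I", "II"),
            "snp": rng.random(n_probes) < snp_fraction,
            "sex_chrom": [c in SEX_CHROMS for c in chroms],
        },
        index=pd.Index([f"cg{i + 1:08d}" for i in range(n_probes)], name="probe"),
    )
    return manifest


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _make_sheet(design: CohortDesign, rng: np.random.Generator) -> pd.DataFrame:
    ids, groups = [], []
    for prefix, group, n in (("B", "benign", design.n_benign),
                             ("A", "APT", design.n_apt),
                             ("P", "PC", design.n_pc)):
        ids += [f"{prefix}{i + 1:03d}" for i in range(n)]
        groups += [group] * n
    n = len(ids)
    batches = [design.batches[i % len(design.batches)] for i in range(n)]
    sheet = pd.DataFrame(
        {
            "sample": ids,
            "group": groups,
            "first_surgery": rng.random(n) < design.first_surgery_fraction,
            "lineage": rng.choice(["PIT1", "TPIT", "SF1"], size=n, p=(0.45, 0.4, 0.15)),
            "functional": rng.choice(["F", "NF"], size=n),
            "slide": batches,
            "array": [f"R{(i // len(design.batches)) % 8 + 1}C1" for i in range(n)],
            "sex": rng.choice(["F", "M"], size=n),
            "age": np.clip(rng.normal(52, 14, size=n), 18, 90).round(1),
        }
    )
    return sheet


def _copy_number(design: CohortDesign, manifest: pd.DataFrame,
                 genome: GenomeSpec, sheet: pd.DataFrame,
                 rng: np.random.Generator):
    """Per-probe, per-sample copy number plus the truth event lists."""
    n_probes, n_samples = len(manifest), len(sheet)
    cn = np.full((n_probes, n_samples), 2.0)
    pos0 = manifest["pos"].to_numpy(np.int64) - 1
    chrom = manifest["chrom"].to_numpy()
    arm_truth = {s: [] for s in sheet["sample"]}
    ct_truth = []

    def expand_arms(label: str) -> list[str]:
        return [f"{label}p", f"{label}q"] if label in genome.lengths else [label]

    for ev in design.arm_events:
        members = sheet.index[sheet["group"] == ev.group].to_numpy()
        if ev.prevalence * len(members) < 1:
            warnings.warn(
                f"prevalence {ev.prevalence} x group size {len(members)} plants "
                f"less than one expected {ev.state} on {ev.arm}; carriers may be zero"
            )
        carry = members[rng.random(len(members)) < ev.prevalence]
        c, start, end = genome.arm_interval(ev.arm)
        mask = (chrom == c) & (pos0 >= start) & (pos0 < end)
        value = 3.0 if ev.state == "gain" else 1.0
        for si in carry:
            cn[mask, si] = value
            for arm in expand_arms(ev.arm):
                arm_truth[sheet.loc[si, "sample"]].append((arm, ev.state))

    for ev in design.chromothripsis:
        members = sheet.index[sheet["group"] == ev.group].to_numpy()
        carry = rng.choice(members, size=min(ev.carriers, len(members)), replace=False)
        length = genome.lengths[ev.chrom]
        edges = np.linspace(0, length, ev.n_segments + 1)
        on_chrom = chrom == ev.chrom
        seg_of_probe = np.clip(
            np.searchsorted(edges, pos0[on_chrom], side="right") - 1, 0, ev.n_segments - 1
        )
        pattern = np.where(np.arange(ev.n_segments) % 2 == 0, 3.0, 1.0)
        for si in carry:
            cn[on_chrom, si] = pattern[seg_of_probe]
            ct_truth.append((sheet.loc[si, "sample"], ev.chrom))
    return cn, arm_truth, ct_truth


def generate_cohort(
    design: CohortDesign,
    manifest: pd.DataFrame,
    genome: GenomeSpec,
) -> tuple[BetaMatrix, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate (beta matrix, intensity matrix, sample sheet, truth).

    Betas follow a three-state beta mixture Beta(mu*s, (1-mu)*s) whose state
    means depend on design type; planted DMP probes have their group means
    shifted by +/- delta_beta, with the sign chosen away from the nearer
    [0, 1] boundary so the planted effect is realizable. Intensities are
    scaled by the purity-mixed copy-number ratio purity*CN/2 + (1 - purity);
    batch shifts are additive on logit(beta).
    """
    if manifest.empty:
        raise ValueError("manifest is empty")
    rng = np.random.default_rng(design.seed)
    sheet = _make_sheet(design, rng)
    n_probes, n_samples = len(manifest), len(sheet)

    state = rng.choice(3, size=n_probes, p=STATE_PROBS)
    t1 = (manifest["design_type"] == "I").to_numpy()
    means_t1 = np.array(STATE_MEANS["I"])[state]
    means_t2 = np.array(STATE_MEANS["II"])[state]
    mu0 = np.where(t1, means_t1, means_t2)

    # plant DMPs on clean autosomal probes so QC does not remove them by design
    eligible = (~manifest["snp"] & ~manifest["sex_chrom"]).to_numpy().nonzero()[0]
    n_dmp = min(design.n_dmp, len(eligible))
    dmp_idx = rng.choice(eligible, size=n_dmp, replace=False) if n_dmp else np.array([], int)
    sign = np.where(mu0[dmp_idx] >= 0.5, -1.0, 1.0)

    mu = np.repeat(mu0[:, None], n_samples, axis=1)
    target = sheet["group"].isin(design.dmp_groups).to_numpy()
    if n_dmp:
        mu[np.ix_(dmp_idx, target.nonzero()[0])] += (sign * design.delta_beta)[:, None]
    mu = np.clip(mu, 1e-3, 1 - 1e-3)

    s = design.dispersion
    betas = rng.beta(mu * s, (1 - mu) * s)

    shifts = np.array([design.batch_shifts.get(b, 0.0) for b in sheet["slide"]])
    if np.any(shifts != 0):
        z = logit(np.clip(betas, 1e-3, 1 - 1e-3)) + shifts[None, :]
        betas = expit(z)

    det = rng.uniform(0, 1e-3, size=(n_probes, n_samples))
    fail = rng.random((n_probes, n_samples)) < design.detection_fail_rate
    det[fail] = rng.uniform(0.02, 0.2, size=int(fail.sum()))

    cn, arm_truth, ct_truth = _copy_number(design, manifest, genome, sheet, rng)
    base = rng.lognormal(mean=np.log(5000), sigma=0.3, size=n_probes)
    ratio = design.purity * cn / 2.0 + (1.0 - design.purity)
    noise = np.exp2(rng.normal(0.0, design.intensity_log2_sd, size=(n_probes, n_samples)))
    intensity = base[:, None] * ratio * noise

    samples = pd.Index(sheet["sample"], name="sample")
    beta = BetaMatrix(
        pd.DataFrame(betas, index=manifest.index, columns=samples),
        pd.DataFrame(det, index=manifest.index, columns=samples),
    )
    intensity_df = pd.DataFrame(intensity, index=manifest.index, columns=samples)
    truth = SyntheticTruth(
        dmp_probes={manifest.index[i]: float(sg * design.delta_beta)
                    for i, sg in zip(dmp_idx, sign)},
        arm_events=arm_truth,
        batches=dict(zip(sheet["sample"], sheet["slide"])),
        chromothripsis=ct_truth,
        groups=dict(zip(sheet["sample"], sheet["group"])),
    )
    return beta, intensity_df, sheet, truth


def summarize_truth(truth: SyntheticTruth) -> pd.DataFrame:
    """Planted-event counts and prevalences per group and arm.

    Also reports the total planted DMP count (one row per group with arm
    ``<DMP>``), so the summary is a single reference table for recovery tests.
    """
    group_sizes = pd.Series(truth.groups).value_counts().to_dict()
    rows = []
    counts: dict = {}
    for sample, events in truth.arm_events.items():
        g = truth.groups[sample]
        for arm, state in set(events):
            counts[(g, arm, state)] = counts.get((g, arm, state), 0) + 1
    for (g, arm, state), n in sorted(counts.items()):
        rows.append((g, arm, state, n, n / group_sizes[g]))
    rows.append(("all", "<DMP>", "planted", len(truth.dmp_probes), float("nan")))
    return pd.DataFrame(rows, columns=["group", "arm", "state", "count", "prevalence"])
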