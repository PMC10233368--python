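"""Synthetic dot-blot screen generator.

Emulates a pairwise proximity-biotinylation screen read out on 1,536-dot
nitrocellulose arrays: two bait strains (e.g. two homologous translocons),
a library of AviTagged preys, three biological by three technical
replicates, two imaging channels per membrane (streptavidin biotinylation
signal and an anti-H3 loading control), and known ground truth for every
planted interaction so the whole analysis chain is testable without any
wet-lab data.

The signal model: each occupied dot deposits an amount of lysate ("load")
proportional to the loading-control channel; the signal channel is
proportional to true interaction strength x load x multiplicative
lognormal noise, rendered as a 2-D Gaussian spot on a planar background
with Gaussian read noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .hydropathy import KD_MAX, KD_MIN, KYTE_DOOLITTLE

CATEGORY_NAMES = ("null", "equal", "prefers_A", "prefers_B")


class CapacityError(ValueError):
    """The requested preys x technical replicates exceed the grid."""


@dataclass
class ScreenConfig:
    """Parameters of a synthetic screen.

    Defaults are the screen's study conditions: a 32 x 48 (1,536-dot)
    array, three biological x three technical replicates (nine replicates
    per bait-prey set), a fourfold true signal difference for preferring
    preys, and 10% multiplicative replicate noise.
    """

    n_preys: int = 512
    grid_rows: int = 32
    grid_cols: int = 48
    n_bio_reps: int = 3
    n_tech_reps: int = 3
    baits: tuple[str, str] = ("baitA", "baitB")
    #: fractions over (null, equal, prefers_A, prefers_B); must sum to 1
    category_fractions: tuple[float, float, float, float] = (0.5, 0.3, 0.1, 0.1)
    true_fold_change: float = 4.0
    #: coefficient of variation of the multiplicative lognormal replicate noise
    replicate_cv: float = 0.1
    #: spread (sigma of log) of per-prey baseline interaction strength
    strength_sigma: float = 0.4
    background_level: float = 200.0
    #: planar background tilt, counts per pixel along each image axis
    background_gradient: float = 0.0
    read_noise_sd: float = 5.0
    dot_sigma_px: float = 3.0
    dot_spacing_px: float = 24.0
    margin_px: float = 30.0
    rotation_deg: float = 0.0
    #: "block": tech reps fill 3 corners of a 2x2 quadrant block (384-well
    #: pinning convention, 4th position empty); "packed": row-major triples
    #: filling the whole grid; "auto" picks block when capacity allows.
    layout: str = "auto"
    missing_strain_fraction: float = 0.01
    od_floor_true: float = 0.05
    #: fraction of occupied dots collapsed to near-zero (failed pin transfer)
    dropout_fraction: float = 0.0
    #: fraction of (bait, prey) sets whose signal channel is collapsed on
    #: every replicate — produces the low-tail Z-score exclusion case
    set_dropout_fraction: float = 0.0
    dropout_factor: float = 1e-3
    #: integrated spot intensity per unit load in the loading-control channel
    control_gain: float = 50000.0
    #: integrated spot intensity per unit (strength x load) in the signal channel
    signal_gain: float = 20000.0
    od_mean: float = 0.5
    od_sd: float = 0.05
    od_missing: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if abs(sum(self.category_fractions) - 1.0) > 1e-9:
            raise ValueError(
                f"category_fractions must sum to 1, got {self.category_fractions}"
            )
        if any(f < 0 for f in self.category_fractions):
            raise ValueError("category_fractions must be nonnegative")
        if self.true_fold_change <= 1:
            raise ValueError("true_fold_change must be > 1")
        for name in (
            "replicate_cv", "strength_sigma", "background_level",
            "background_gradient", "read_noise_sd", "missing_strain_fraction",
            "dropout_fraction", "set_dropout_fraction",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_preys < 1 or self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("n_preys, grid_rows, grid_cols must be >= 1")
        if self.layout not in ("auto", "block", "packed"):
            raise ValueError(f"unknown layout {self.layout!r}")
        capacity = self.grid_rows * self.grid_cols
        if self.n_preys * self.n_tech_reps > capacity:
            raise CapacityError(
                f"{self.n_preys} preys x {self.n_tech_reps} technical replicates "
                f"exceed the {self.grid_rows}x{self.grid_cols}={capacity} grid"
            )
        if self.layout == "block" and not self._block_fits():
            raise CapacityError(
                "block layout cannot hold "
                f"{self.n_preys} preys x {self.n_tech_reps} replicates"
            )

    def _block_fits(self) -> bool:
        n_blocks = (self.grid_rows // 2) * (self.grid_cols // 2)
        return self.n_tech_reps <= 4 and self.n_preys <= n_blocks

    @property
    def image_shape(self) -> tuple[int, int]:
        h = int(round(2 * self.margin_px + (self.grid_rows - 1) * self.dot_spacing_px)) + 1
        w = int(round(2 * self.margin_px + (self.grid_cols - 1) * self.dot_spacing_px)) + 1
        return h, w

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["baits"] = list(self.baits)
        d["category_fractions"] = list(self.category_fractions)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScreenConfig":
        d = dict(d)
        if "baits" in d:
            d["baits"] = tuple(d["baits"])
        if "category_fractions" in d:
            d["category_fractions"] = tuple(d["category_fractions"])
        return cls(**d)


@dataclass
class SyntheticGroundTruth:
    """Planted truth keyed by prey and (bait, prey).

    ``preys``: prey_id, category, base_strength.
    ``signals``: bait_id, prey_id, true_signal, is_missing_strain,
    is_set_dropout. For a prefers_A prey, true_signal(A)/true_signal(B)
    equals the configured fold change; equal preys have ratio 1; null preys
    have zero signal for both baits.
    ``dots``: per occupied dot, the rendered (background-free) integrated
    intensity of each channel — the oracle for quantification tests.
    ``dropout_positions``: grid coordinates of planted per-dot dropouts.
    """

    preys: pd.DataFrame
    signals: pd.DataFrame
    dots: pd.DataFrame
    dropout_positions: pd.DataFrame


@dataclass
class SyntheticScreen:
    """Everything one screen run produces: images, tables, truth."""

    config: ScreenConfig
    images: dict[str, np.ndarray]  # membrane_id -> (2, H, W) uint16
    plate_map: pd.DataFrame
    od_table: pd.DataFrame
    truth: SyntheticGroundTruth

    def membrane_ids(self) -> list[str]:
        return list(self.images)


def _category_counts(fractions: Sequence[float], n: int) -> list[int]:
    """Largest-remainder apportionment: counts == round(frac * n), sum == n."""
    raw = [f * n for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    remainder = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def assign_categories(config: ScreenConfig, rng: np.random.Generator) -> pd.DataFrame:
    counts = _category_counts(config.category_fractions, config.n_preys)
    labels = np.repeat(CATEGORY_NAMES, counts)
    labels = labels[rng.permutation(config.n_preys)]
    strength = np.exp(rng.normal(0.0, config.strength_sigma, config.n_preys))
    strength[labels == "null"] = 0.0
    return pd.DataFrame(
        {
            "prey_id": [f"prey{i:04d}" for i in range(config.n_preys)],
            "category": labels,
            "base_strength": strength,
        }
    )


def true_signals(preys: pd.DataFrame, config: ScreenConfig) -> pd.DataFrame:
    """Per-(bait, prey) planted interaction strength from prey categories."""
    bait_a, bait_b = config.baits
    fc = config.true_fold_change
    rows = []
    for rec in preys.itertuples():
        s = rec.base_strength
        if rec.category == "null":
            sig_a = sig_b = 0.0
        elif rec.category == "equal":
            sig_a = sig_b = s
        elif rec.category == "prefers_A":
            sig_a, sig_b = s * fc, s
        else:
            sig_a, sig_b = s, s * fc
        rows.append((bait_a, rec.prey_id, sig_a))
        rows.append((bait_b, rec.prey_id, sig_b))
    return pd.DataFrame(rows, columns=["bait_id", "prey_id", "true_signal"])


def layout_positions(config: ScreenConfig) -> pd.DataFrame:
    """Grid position of every technical replicate of every prey (0-based)."""
    mode = config.layout
    if mode == "auto":
        mode = "block" if config._block_fits() else "packed"
    rows = []
    if mode == "block":
        block_cols = config.grid_cols // 2
        offsets = [(0, 0), (0, 1), (1, 0), (1, 1)][: config.n_tech_reps]
        for i in range(config.n_preys):
            br, bc = divmod(i, block_cols)
            for t, (dr, dc) in enumerate(offsets, start=1):
                rows.append((i, t, 2 * br + dr, 2 * bc + dc))
    else:
        for i in range(config.n_preys):
            for t in range(1, config.n_tech_reps + 1):
                pos = i * config.n_tech_reps + (t - 1)
                r, c = divmod(pos, config.grid_cols)
                rows.append((i, t, r, c))
    return pd.DataFrame(rows, columns=["prey_index", "tech_rep", "row0", "col0"])


def grid_centers(config: ScreenConfig) -> np.ndarray:
    """(rows, cols, 2) array of (x, y) dot centers, rotation applied."""
    r = np.arange(config.grid_rows)
    c = np.arange(config.grid_cols)
    cc, rr = np.meshgrid(c, r)
    x = config.margin_px + cc * config.dot_spacing_px
    y = config.margin_px + rr * config.dot_spacing_px
    theta = np.deg2rad(config.rotation_deg)
    if theta != 0.0:
        h, w = config.image_shape
        cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
        xr = cx + (x - cx) * np.cos(theta) - (y - cy) * np.sin(theta)
        yr = cy + (x - cx) * np.sin(theta) + (y - cy) * np.cos(theta)
        x, y = xr, yr
    return np.stack([x, y], axis=-1)


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(-sigma * sigma / 2.0, sigma, size))


def _render_spots(
    shape: tuple[int, int],
    centers: np.ndarray,
    integrals: np.ndarray,
    sigma: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Add truncated (3 sigma) Gaussian spots; return image and actual sums."""
    img = np.zeros(shape, dtype=float)
    h, w = shape
    half = int(np.ceil(3 * sigma))
    rendered = np.zeros(len(centers))
    for i, ((x, y), total) in enumerate(zip(centers, integrals)):
        if total <= 0:
            continue
        x0, y0 = int(np.floor(x)), int(np.floor(y))
        xs = np.arange(max(x0 - half, 0), min(x0 + half + 2, w))
        ys = np.arange(max(y0 - half, 0), min(y0 + half + 2, h))
        gx, gy = np.meshgrid(xs, ys)
        d2 = (gx - x) ** 2 + (gy - y) ** 2
        patch = np.exp(-d2 / (2 * sigma * sigma))
        patch[d2 > (3 * sigma) ** 2] = 0.0
        amp = total / (2 * np.pi * sigma * sigma)
        patch *= amp
        img[ys[0]: ys[-1] + 1, xs[0]: xs[-1] + 1] += patch
        rendered[i] = patch.sum()
    return img, rendered


def _background(shape: tuple[int, int], config: ScreenConfig) -> np.ndarray:
    h, w = shape
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    return config.background_level + config.background_gradient * (xx + yy)


def generate_screen(
    config: ScreenConfig, preys: pd.DataFrame | None = None
) -> SyntheticScreen:
    """Simulate a full two-bait screen.

    Returns membrane images (one per bait x biological replicate, two
    channels each), the plate map, the pre-lysis OD table and the planted
    ground truth. Identical config (including seed) gives byte-identical
    output. ``preys`` may preset the per-prey table (prey_id, category,
    base_strength), e.g. to plant reporter constructs inheriting a donor's
    preference.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if preys is None:
        preys = assign_categories(config, rng)
    else:
        preys = preys.reset_index(drop=True)
        if len(preys) != config.n_preys:
            raise ValueError("preset preys table does not match n_preys")
        rng.permutation(config.n_preys)  # keep stream alignment with default path
        rng.normal(0.0, config.strength_sigma, config.n_preys)

    signals = true_signals(preys, config)
    n_pairs = len(signals)
    signals["is_missing_strain"] = (
        rng.random(n_pairs) < config.missing_strain_fraction
    )
    signals["is_set_dropout"] = rng.random(n_pairs) < config.set_dropout_fraction

    od = np.maximum(rng.normal(config.od_mean, config.od_sd, n_pairs), 0.0)
    od[signals["is_missing_strain"].to_numpy()] = config.od_missing
    od_table = pd.DataFrame(
        {
            "strain_id": signals["bait_id"] + ":" + signals["prey_id"],
            "od600": od,
        }
    )

    layout = layout_positions(config)
    centers = grid_centers(config)
    shape = config.image_shape
    background = _background(shape, config)

    images: dict[str, np.ndarray] = {}
    map_rows = []
    dot_rows = []
    dropout_rows = []
    prey_ids = preys["prey_id"].to_numpy()

    layout_rows = layout["row0"].to_numpy()
    layout_cols = layout["col0"].to_numpy()
    layout_prey = layout["prey_index"].to_numpy()
    layout_tech = layout["tech_rep"].to_numpy()

    for bait in config.baits:
        sub = signals[signals["bait_id"] == bait]
        true_sig_all = sub["true_signal"].to_numpy()[layout_prey]
        missing = sub["is_missing_strain"].to_numpy()[layout_prey]
        setdrop = sub["is_set_dropout"].to_numpy()[layout_prey]
        for bio in range(1, config.n_bio_reps + 1):
            mem_id = f"{bait}_b{bio}"
            n_dots = len(layout)
            true_sig = true_sig_all
            load = np.where(missing, 0.01, 1.0) * _lognormal_factor(
                rng, config.replicate_cv, n_dots
            )
            noise = _lognormal_factor(rng, config.replicate_cv, n_dots)
            dot_dropout = rng.random(n_dots) < config.dropout_fraction
            load = np.where(dot_dropout, load * config.dropout_factor, load)
            control_I = config.control_gain * load
            signal_I = config.signal_gain * true_sig * load * noise
            signal_I = np.where(setdrop, signal_I * config.dropout_factor, signal_I)

            dot_centers = centers[layout["row0"].to_numpy(), layout["col0"].to_numpy()]
            sig_img, sig_sum = _render_spots(
                shape, dot_centers, signal_I, config.dot_sigma_px
            )
            ctl_img, ctl_sum = _render_spots(
                shape, dot_centers, control_I, config.dot_sigma_px
            )
            pages = []
            for chan in (sig_img, ctl_img):
                img = chan + background
                if config.read_noise_sd > 0:
                    img = img + rng.normal(0.0, config.read_noise_sd, shape)
                pages.append(np.clip(np.round(img), 0, 65535).astype(np.uint16))
            images[mem_id] = np.stack(pages)

            for j, rec in enumerate(layout.itertuples()):
                map_rows.append(
                    (
                        mem_id,
                        rec.row0 + 1,
                        rec.col0 + 1,
                        bait,
                        prey_ids[rec.prey_index],
                        bio,
                        rec.tech_rep,
                    )
                )
                dot_rows.append(
                    (mem_id, rec.row0 + 1, rec.col0 + 1, sig_sum[j], ctl_sum[j])
                )
                if dot_dropout[j]:
                    dropout_rows.append((mem_id, rec.row0 + 1, rec.col0 + 1))

    plate_map = pd.DataFrame(
        map_rows,
        columns=[
            "membrane_id", "row", "col", "bait_id", "prey_id", "bio_rep", "tech_rep",
        ],
    )
    truth = SyntheticGroundTruth(
        preys=preys,
        signals=signals,
        dots=pd.DataFrame(
            dot_rows,
            columns=[
                "membrane_id", "row", "col",
                "signal_integrated", "control_integrated",
            ],
        ),
        dropout_positions=pd.DataFrame(
            dropout_rows, columns=["membrane_id", "row", "col"]
        ),
    )
    return SyntheticScreen(
        config=config,
        images=images,
        plate_map=plate_map,
        od_table=od_table,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Synthetic signal-peptide sets


_AA = sorted(KYTE_DOOLITTLE)
_AA_VALUES = np.array([KYTE_DOOLITTLE[a] for a in _AA])


def _boltzmann_weights(target: float) -> np.ndarray:
    """Residue probabilities whose expected hydropathy equals ``target``.

    Exponential tilting of the uniform distribution over the 20 standard
    residues: p_i proportional to exp(lambda * kd_i), with lambda solved so
    the mean matches. The mean is monotone in lambda and spans the open
    interval (-4.5, 4.5); the endpoints are handled as point masses.
    """
    if not (KD_MIN <= target <= KD_MAX):
        raise ValueError(
            f"target hydropathy {target} outside the scale range "
            f"[{KD_MIN}, {KD_MAX}]"
        )
    if target == KD_MAX:
        return (_AA_VALUES == KD_MAX).astype(float)
    if target == KD_MIN:
        return (_AA_VALUES == KD_MIN).astype(float)

    def mean_at(lam: float) -> float:
        w = np.exp(lam * (_AA_VALUES - _AA_VALUES.max()))
        return float(np.sum(w * _AA_VALUES) / np.sum(w)) - target

    lam = brentq(mean_at, -40.0, 40.0, xtol=1e-10)
    w = np.exp(lam * (_AA_VALUES - _AA_VALUES.max()))
    return w / w.sum()


def generate_sp_set(
    n_per_group: int,
    length: int,
    group_profiles: Mapping[str, Sequence[float] | float],
    seed: int = 0,
) -> dict[str, list[str]]:
    """Sample labelled signal-peptide sets with target hydropathy profiles.

    Each group's sequences are drawn residue-by-residue from exponentially
    tilted distributions whose per-position expected Kyte-Doolittle value
    equals that position's target, so the group's empirical profile
    converges to the target as ``n_per_group`` grows. Scalar targets are
    broadcast; shorter target vectors are extended with their last value.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    out: dict[str, list[str]] = {}
    for label in group_profiles:
        targets = group_profiles[label]
        if np.isscalar(targets):
            targets = [float(targets)] * length
        targets = list(targets)
        if len(targets) < length:
            targets = targets + [targets[-1]] * (length - len(targets))
        targets = targets[:length]
        probs = [_boltzmann_weights(t) for t in targets]
        seqs = []
        for _ in range(n_per_group):
            idx = [rng.choice(20, p=p) for p in probs]
            seqs.append("".join(_AA[i] for i in idx))
        out[label] = seqs
    return out


#: Default per-position hydropathy targets used when simulating annotation
#: tables: the groups share a hydrophobic SP core but differ in the first
#: three residues, the region the prefix-swap experiment manipulates.
DEFAULT_SP_TARGETS: Mapping[str, list[float]] = {
    "prefers_A": [-1.0, -1.0, -1.0] + [2.5] * 12 + [0.0] * 5,
    "prefers_B": [2.0, 2.0, 2.0] + [2.5] * 12 + [0.0] * 5,
    "both": [0.5, 0.5, 0.5] + [2.5] * 12 + [0.0] * 5,
}


def synthetic_annotations(
    preys: pd.DataFrame,
    seed: int = 0,
    sp_length: int = 20,
    targets: Mapping[str, Sequence[float]] = DEFAULT_SP_TARGETS,
    mts_fraction: float = 0.05,
) -> pd.DataFrame:
    """Feature-annotation table matching a planted prey table.

    Interacting preys (equal / preferring) carry a signal peptide drawn
    from their category's target hydropathy profile; null preys carry no
    SP/TMD. A small fraction of preys get an MTS flag so the substrate
    filter has something to remove.
    """
    rng = np.random.default_rng(seed)
    cat_to_group = {"equal": "both", "prefers_A": "prefers_A", "prefers_B": "prefers_B"}
    rows = []
    for rec in preys.itertuples():
        group = cat_to_group.get(rec.category)
        if group is None:
            rows.append((rec.prey_id, False, False, False, ""))
            continue
        seqs = generate_sp_set(
            1, sp_length, {group: targets[group]},
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        has_mts = bool(rng.random() < mts_fraction)
        rows.append((rec.prey_id, True, False, has_mts, seqs[group][0]))
    return pd.DataFrame(
        rows, columns=["protein_id", "has_sp", "has_tmd", "has_mts", "sp_sequence"]
    )
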