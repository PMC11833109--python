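"""Synthetic 3D-IFC dataset generator.

Emulates the data a 3D imaging flow cytometer plus cell placement
platform produces for single CHO cells, at desk scale:

* a 10-slice 3D side-scatter (SSC) volume per cell — a soft-edged
  ellipsoid intensity envelope with Poisson-count scattering centers
  per slice, each rendered as a Gaussian blob;
* a 2D transmission image — the depth-projected silhouette with
  texture noise;
* GFP fluorescence at 0 h and 48 h (production scenario only), whose
  difference is the protein production rate; the rate is drawn from a
  two-component mixture whose upper component is the positive class;
* an interleaved cell/marker-bead dispense sequence at a configurable
  cell-to-bead ratio (~2:1 by default), and a copy of it perturbed by
  deletion and displacement errors, standing in for the sequence read
  off the placement membrane.

Class-conditional structure: the positive class shifts three
morphological parameters — scattering-center rate per slice, center
intensity, and the cell-radius proxy — by ``effect_size`` times a
per-parameter gap, scaled per scenario (glucose deprivation shifts
more than thermal stress, reflecting the much stronger separability of
glucose-deprived cells).  With ``effect_size = 0`` the two classes are
generated from identical distributions.

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .config import SCENARIO_MORPH_SCALE, SimConfig, derive_seed
from .errors import InputError
from .sequences import BEAD, CELL, DispenseSequence, Token, bead, cell

# --- class-conditional generative parameters (per unit effect_size) ---
BASE_CENTER_RATE = 4.0       # Poisson scattering centers per slice, class 0
CENTER_RATE_GAP = 1.0        # added to the rate per unit effect_size (class 1)
BASE_CENTER_AMP = 1.0        # scattering-center peak amplitude, class 0
CENTER_AMP_GAP = 0.15        # amplitude shift per unit effect_size
BASE_RADIUS_FRAC = 0.30      # cell radius as fraction of half the image extent
RADIUS_FRAC_GAP = 0.035      # radius shift per unit effect_size
ENVELOPE_AMP = 0.25          # peak intensity of the ellipsoid envelope
CENTER_SIGMA = 0.8           # Gaussian blur (pixels) applied to center impulses

# --- GFP production-rate mixture (fluorescence units over 48 h) ---
RATE_LOW_MEAN, RATE_LOW_SD = 50.0, 15.0
RATE_HIGH_MEAN, RATE_HIGH_SD = 110.0, 20.0
FL0_LOG_MEAN, FL0_LOG_SD = 3.9, 0.25


def class_center_rates(config: SimConfig) -> tuple[float, float]:
    """Per-slice Poisson scattering-center rates for class 0 and class 1.

    The class-1 rate exceeds the class-0 rate by
    ``effect_size * CENTER_RATE_GAP`` scaled by the scenario's
    morphology-gap preset.  Exposed so callers can re-draw counts from
    the same distributions (e.g. for Monte-Carlo checks).
    """
    scale = SCENARIO_MORPH_SCALE[config.scenario]
    lam0 = BASE_CENTER_RATE
    lam1 = BASE_CENTER_RATE + config.effect_size * CENTER_RATE_GAP * scale
    return lam0, lam1


def _class_params(config: SimConfig, cls: int) -> tuple[float, float, float]:
    """(center rate, center amplitude, radius fraction) for one class."""
    scale = SCENARIO_MORPH_SCALE[config.scenario]
    shift = config.effect_size * scale * cls
    return (
        BASE_CENTER_RATE + CENTER_RATE_GAP * shift,
        BASE_CENTER_AMP + CENTER_AMP_GAP * shift,
        BASE_RADIUS_FRAC + RADIUS_FRAC_GAP * shift,
    )


@dataclass
class CellRecord:
    """One simulated cell: images, fluorescence, labels, dispense order."""

    cell_id: int
    ssc_image: np.ndarray      # (depth, H, W) float32, values in [0, 1]
    trans_image: np.ndarray    # (H, W) float32, values in [0, 1]
    fl_0h: float
    fl_48h: float
    true_class: int
    scenario_label: str
    dispense_index: int
    center_counts: np.ndarray | None = None   # scattering centers per slice

    def __post_init__(self) -> None:
        if self.ssc_image.ndim != 3:
            raise InputError("ssc_image must be a 3D (depth, H, W) array")
        if np.any(self.ssc_image < 0) or np.any(self.trans_image < 0):
            raise InputError("image intensities must be non-negative")
        if not (np.isfinite(self.fl_0h) and np.isfinite(self.fl_48h)):
            raise InputError("fluorescence values must be finite")
        if self.fl_0h < 0 or self.fl_48h < 0:
            raise InputError("fluorescence values must be non-negative")


def _render_ssc(rng: np.random.Generator, config: SimConfig,
                lam: float, amp: float, radius_frac: float
                ) -> tuple[np.ndarray, np.ndarray]:
    """Render one cell's 3D SSC volume; returns (volume, per-slice counts)."""
    d, h, w = config.image_depth, config.image_height, config.image_width
    half = min(h, w) / 2.0
    ry = radius_frac * half * rng.uniform(0.85, 1.15)
    rx = radius_frac * half * rng.uniform(0.85, 1.15)
    rd = max(d / 2.0 * rng.uniform(0.8, 1.0), 0.75)
    cz = (d - 1) / 2.0 + rng.uniform(-0.05, 0.05) * d
    cy = (h - 1) / 2.0 + rng.uniform(-0.05, 0.05) * h
    cx = (w - 1) / 2.0 + rng.uniform(-0.05, 0.05) * w

    zz = (np.arange(d)[:, None, None] - cz) / rd
    yy = (np.arange(h)[None, :, None] - cy) / ry
    xx = (np.arange(w)[None, None, :] - cx) / rx
    rho = np.sqrt(zz**2 + yy**2 + xx**2)
    vol = ENVELOPE_AMP / (1.0 + np.exp((rho - 1.0) / 0.08))

    counts = rng.poisson(lam, size=d)
    impulses = np.zeros((d, h, w))
    for z in range(d):
        # cross-section of the ellipsoid at this slice; floor keeps a
        # minimal footprint so centers can land on every slice
        sz = np.sqrt(max(1.0 - ((z - cz) / rd) ** 2, 0.0))
        sz = max(sz, 0.15)
        for _ in range(counts[z]):
            theta = rng.uniform(0, 2 * np.pi)
            r = np.sqrt(rng.uniform())   # uniform over the ellipse disk
            py = cy + r * sz * ry * np.sin(theta)
            px = cx + r * sz * rx * np.cos(theta)
            iy = int(np.clip(round(py), 0, h - 1))
            ix = int(np.clip(round(px), 0, w - 1))
            impulses[z, iy, ix] += amp * rng.uniform(0.7, 1.3)
    blurred = gaussian_filter(impulses, sigma=(0, CENTER_SIGMA, CENTER_SIGMA))
    vol = vol + blurred
    if config.noise_sd > 0:
        vol = vol + rng.normal(0.0, config.noise_sd, size=vol.shape)
    vol = np.clip(vol, 0.0, None)
    peak = vol.max()
    if peak > 0:
        vol = vol / peak
    return vol.astype(np.float32), counts


def _render_trans(rng: np.random.Generator, config: SimConfig,
                  radius_frac: float) -> np.ndarray:
    """Render the 2D transmission silhouette of one cell."""
    h, w = config.trans_height, config.trans_width
    half = min(h, w) / 2.0
    ry = radius_frac * half * rng.uniform(0.85, 1.15)
    rx = radius_frac * half * rng.uniform(0.85, 1.15)
    cy = (h - 1) / 2.0 + rng.uniform(-0.05, 0.05) * h
    cx = (w - 1) / 2.0 + rng.uniform(-0.05, 0.05) * w
    yy = (np.arange(h)[:, None] - cy) / ry
    xx = (np.arange(w)[None, :] - cx) / rx
    rho = np.sqrt(yy**2 + xx**2)
    body = 0.8 / (1.0 + np.exp((rho - 1.0) / 0.06))
    texture = gaussian_filter(rng.normal(0.0, 1.0, size=(h, w)), 1.0)
    img = body * (1.0 + 0.1 * texture)
    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, None)
    peak = img.max()
    if peak > 0:
        img = img / peak
    return img.astype(np.float32)


def simulate_population(config: SimConfig) -> list[CellRecord]:
    """Generate ``config.n_cells`` cell records.

    Exactly ``round(class_fraction * n_cells)`` cells are positive
    class.  In the ``gfp_production`` scenario the production rate
    ``fl_48h - fl_0h`` is drawn from a two-component Gaussian mixture
    whose upper component is the positive class; in the stress
    scenarios fluorescence is unused (set to 0) and only morphology
    carries the class signal.
    """
    n = config.n_cells
    if n == 0:
        return []
    root = np.random.SeedSequence(config.seed)
    assign_ss, cells_ss = root.spawn(2)
    rng_assign = np.random.default_rng(assign_ss)

    n_pos = int(round(config.class_fraction * n))
    classes = np.zeros(n, dtype=int)
    classes[:n_pos] = 1
    rng_assign.shuffle(classes)

    records: list[CellRecord] = []
    for i, cell_ss in enumerate(cells_ss.spawn(n)):
        rng = np.random.default_rng(cell_ss)
        cls = int(classes[i])
        lam, amp, radius_frac = _class_params(config, cls)
        ssc, counts = _render_ssc(rng, config, lam, amp, radius_frac)
        trans = _render_trans(rng, config, radius_frac)
        if config.scenario == "gfp_production":
            fl0 = float(rng.lognormal(FL0_LOG_MEAN, FL0_LOG_SD))
            if cls == 1:
                rate = rng.normal(RATE_HIGH_MEAN, RATE_HIGH_SD)
            else:
                rate = rng.normal(RATE_LOW_MEAN, RATE_LOW_SD)
            fl48 = float(max(fl0 + rate, 0.0))
        else:
            fl0 = fl48 = 0.0
        records.append(CellRecord(
            cell_id=i, ssc_image=ssc, trans_image=trans,
            fl_0h=fl0, fl_48h=fl48, true_class=cls,
            scenario_label=config.scenario, dispense_index=i,
            center_counts=counts,
        ))
    return records


@dataclass
class SimulatedDispense:
    """IFC and CPP dispense sequences plus the ground-truth perturbations.

    Iterable as the ``(ifc, cpp)`` pair; the deleted/displaced cell-id
    sets record which cells were perturbed when deriving the CPP
    sequence from the IFC sequence.
    """

    ifc: DispenseSequence
    cpp: DispenseSequence
    deleted_cells: set[int] = field(default_factory=set)
    displaced_cells: set[int] = field(default_factory=set)

    def __iter__(self):
        return iter((self.ifc, self.cpp))


def simulate_dispense(records: list[CellRecord],
                      config: SimConfig) -> SimulatedDispense:
    """Interleave cells with marker beads; perturb a copy with errors.

    The IFC sequence dispenses all cells in order, inserting a bead
    before each slot by a Bernoulli process with probability
    ``1 / (1 + cell_to_bead_ratio)`` per draw, so the realized
    cell:bead ratio approximates the configured ratio; the first and
    last tokens are forced to be beads so every cell lies in a
    bead-delimited segment.  The CPP sequence is derived by deleting
    each cell independently with ``deletion_rate`` and, with
    ``displacement_rate`` per interior bead, letting the cell just
    before the bead hop across it (a cell/bead swap), which scrambles
    that cell into the neighbouring segment.
    """
    if not records:
        raise InputError("simulate_dispense requires a non-empty record list")
    rng = np.random.default_rng(derive_seed("dispense", config.seed))
    p_bead = 1.0 / (1.0 + config.cell_to_bead_ratio)
    labels = list(config.bead_types)

    def draw_bead() -> Token:
        return bead(labels[rng.integers(len(labels))])

    tokens: list[Token] = [draw_bead()]
    for rec in records:
        while rng.random() < p_bead:
            tokens.append(draw_bead())
        tokens.append(cell(rec.cell_id))
    tokens.append(draw_bead())
    ifc = DispenseSequence(tokens)

    deleted: set[int] = set()
    kept: list[Token] = []
    for tok in ifc.tokens:
        if tok.kind == CELL and rng.random() < config.deletion_rate:
            deleted.add(tok.ref_id)
        else:
            kept.append(tok)

    displaced: set[int] = set()
    cpp_tokens = list(kept)
    i = 1
    while i < len(cpp_tokens) - 1:
        tok = cpp_tokens[i]
        prev = cpp_tokens[i - 1]
        if (tok.kind == BEAD and prev.kind == CELL
                and rng.random() < config.displacement_rate):
            cpp_tokens[i - 1], cpp_tokens[i] = tok, prev
            displaced.add(prev.ref_id)
            i += 1   # the swapped cell is not displaced twice
        i += 1
    return SimulatedDispense(ifc, DispenseSequence(cpp_tokens),
                             deleted, displaced)
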