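"""Synthetic 19F oximetry studies with known ground truth.

The generator emulates the study design the analysis assumes: two genotypes
(WT: 3 mothers / 19 placentas; KO: 4 mothers / 17 placentas), three
within-subject oxygen conditions (30/60/100% O2 in breathing air) and a
four-TR saturation-recovery acquisition (318/719/1398/5000 ms) on the coarse
19F matrix, with placenta ROIs drawn on the fine anatomical matrix.

Per placenta and condition the true PO2 is

    PO2 = baseline(oxygen) + KO offset(oxygen) + b_mother + b_placenta + e

with Normal mother-, placenta- and condition-level deviations, and the true
T1 follows exactly from the PFCE calibration.  Noiseless voxel signal inside
placenta p is ``S(TR) = S0 * (1 - exp(-TR/T1))``; measured magnitude is
Rician, ``|S + n1 + i n2|`` with independent Gaussian ``n1, n2`` of SD
``sigma_g`` — the noise model the downstream Gudbjartsson-Patz correction
presumes.  Background voxels carry pure noise.

Every placenta is homogeneous per condition (no within-placenta PO2
texture) and there is no motion, field inhomogeneity or chemical-shift
artefact: passing tests on these phantoms validates the estimation chain,
not robustness to those real-data effects.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import DEFAULT_CALIBRATION, OxygenCalibration, po2_to_t1
from .image_io import (
    ANATOMICAL_GRID,
    FLUORINE_GRID,
    GridSpec,
    MagnitudeSeries,
    RoiSet,
    validate_design_table,
)

__all__ = [
    "CompartmentModel",
    "PhantomConfig",
    "StudyBundle",
    "mix_compartments",
    "saturation_recovery_signal",
    "generate_study",
    "simulate_records",
]

BACKGROUND_LABEL = 999


def saturation_recovery_signal(tr_ms, s0: float, t1_s: float) -> np.ndarray:
    """Noiseless saturation-recovery curve S0 * (1 - exp(-TR/T1))."""
    tr = np.asarray(tr_ms, dtype=float) / 1000.0
    return s0 * (1.0 - np.exp(-tr / t1_s))


@dataclass(frozen=True)
class CompartmentModel:
    """Three-pool placenta signal model (maternal, fetal, trophoblast).

    ``volume_fractions`` must be nonnegative and sum to 1; ``t1_s`` is the
    per-pool T1 and ``weights`` the per-pool relative 19F concentration.
    Defaults use the literature volume fractions 64.4/23.7/11.9%.
    """

    volume_fractions: tuple[float, ...] = (0.644, 0.237, 0.119)
    t1_s: tuple[float, ...] = (1.5, 0.8, 2.5)
    weights: tuple[float, ...] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        f = np.asarray(self.volume_fractions, dtype=float)
        if len(self.t1_s) != f.size or len(self.weights) != f.size:
            raise ValueError("fractions, t1_s and weights must align")
        if np.any(f < 0):
            raise ValueError("volume fractions must be nonnegative")
        if abs(f.sum() - 1.0) > 1e-12:
            raise ValueError("volume fractions must sum to 1 within 1e-12")
        if np.any(np.asarray(self.t1_s) <= 0):
            raise ValueError("compartment T1s must be positive")


def mix_compartments(model: CompartmentModel, tr_list_ms, s0: float = 1.0) -> np.ndarray:
    """Noiseless multi-compartment signal S(TR) = s0 * sum_c w_c f_c (1 - exp(-TR/T1_c)).

    Collapses to the single-compartment curve when one fraction is 1 or all
    T1s coincide (given unit weights).
    """
    tr = np.asarray(tr_list_ms, dtype=float)
    out = np.zeros_like(tr)
    for f, t1, w in zip(model.volume_fractions, model.t1_s, model.weights):
        out += w * f * saturation_recovery_signal(tr, 1.0, t1)
    return s0 * out


@dataclass(frozen=True)
class PhantomConfig:
    """Study-design and noise parameters of the synthetic phantom.

    Defaults reproduce the study conditions: design sizes, TRs, acquisition
    geometry, study-realistic oxygen-level means and a KO deficit of -64 mmHg at
    30% O2 only.  PO2 heterogeneity is Normal at three levels (mother,
    placenta, condition residual).
    """

    n_mothers: tuple[int, int] = (3, 4)          # (WT, KO)
    n_placentas: tuple[int, int] = (19, 17)      # (WT, KO) totals
    placentas_per_mother: tuple[int, int] | None = None  # sampling-range mode
    oxygen_levels: tuple[float, ...] = (30.0, 60.0, 100.0)
    tr_list_ms: tuple[float, ...] = (318.0, 719.0, 1398.0, 5000.0)
    baseline_po2_mmhg: tuple[float, ...] = (100.0, 150.0, 250.0)
    ko_po2_offset_mmhg: tuple[float, ...] = (-64.0, 0.0, 0.0)
    sd_mother_mmhg: float = 10.0
    sd_placenta_mmhg: float = 20.0
    sd_residual_mmhg: float = 15.0
    sigma_g: float = 1.0                         # native-unit Gaussian noise SD
    s0_range: tuple[float, float] = (8.0, 16.0)  # native units (SNR-equivalent)
    seed: int = 0
    anat_grid: GridSpec = ANATOMICAL_GRID
    f19_grid: GridSpec = FLUORINE_GRID
    compartments: CompartmentModel | None = None
    calibration: OxygenCalibration = DEFAULT_CALIBRATION

    def validate(self) -> "PhantomConfig":
        if len(set(self.oxygen_levels)) != len(self.oxygen_levels):
            raise ValueError("oxygen levels must be distinct")
        if np.any(np.asarray(self.tr_list_ms) <= 0):
            raise ValueError("all TRs must be positive")
        if self.sigma_g < 0:
            raise ValueError("sigma_g must be nonnegative")
        if len(self.baseline_po2_mmhg) != len(self.oxygen_levels):
            raise ValueError("need one baseline PO2 per oxygen level")
        if len(self.ko_po2_offset_mmhg) != len(self.oxygen_levels):
            raise ValueError("need one KO offset per oxygen level")
        means = np.asarray(self.baseline_po2_mmhg)
        for geno_means in (means, means + np.asarray(self.ko_po2_offset_mmhg)):
            if np.any(geno_means <= -self.calibration.intercept):
                raise ValueError(
                    "configured mean PO2 implies a nonpositive T1 "
                    f"(PO2 must exceed {-self.calibration.intercept:.2f} mmHg)"
                )
        if self.s0_range[0] <= 0 or self.s0_range[1] < self.s0_range[0]:
            raise ValueError("s0_range must be a positive increasing pair")
        if any(n < 1 for n in self.n_mothers):
            raise ValueError("need at least one mother per genotype")
        return self

    def replace(self, **kw) -> "PhantomConfig":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# Ground-truth tables


def _placenta_counts(config: PhantomConfig, rng: np.random.Generator) -> dict[str, list[int]]:
    """Number of placentas per mother, by genotype.

    Default mode distributes the configured per-genotype totals as evenly as
    possible across mothers; range mode samples uniformly per mother.
    """
    counts: dict[str, list[int]] = {}
    for geno, n_m, n_p in zip(("WT", "KO"), config.n_mothers, config.n_placentas):
        if config.placentas_per_mother is not None:
            lo, hi = config.placentas_per_mother
            counts[geno] = [int(rng.integers(lo, hi + 1)) for _ in range(n_m)]
        else:
            base, extra = divmod(n_p, n_m)
            counts[geno] = [base + (1 if i < extra else 0) for i in range(n_m)]
    return counts


def _sample_truth(config: PhantomConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per placenta x condition ground-truth table (PO2, T1, S0)."""
    counts = _placenta_counts(config, rng)
    oxy = np.asarray(config.oxygen_levels, dtype=float)
    baseline = {o: b for o, b in zip(config.oxygen_levels, config.baseline_po2_mmhg)}
    ko_offset = {o: d for o, d in zip(config.oxygen_levels, config.ko_po2_offset_mmhg)}
    floor = -config.calibration.intercept + 5.0  # keep implied T1 finite/positive

    rows = []
    label = 0
    for geno in ("WT", "KO"):
        for i_m, n_p in enumerate(counts[geno]):
            mother = f"{geno}{i_m + 1}"
            b_mother = rng.normal(0.0, config.sd_mother_mmhg)
            for i_p in range(n_p):
                label += 1
                placenta = f"{mother}-P{i_p + 1}"
                b_plac = rng.normal(0.0, config.sd_placenta_mmhg)
                s0 = rng.uniform(*config.s0_range)
                for o in oxy:
                    mean = baseline[o] + (ko_offset[o] if geno == "KO" else 0.0)
                    po2 = mean + b_mother + b_plac + rng.normal(0.0, config.sd_residual_mmhg)
                    while po2 <= floor:  # redraw condition residual if unphysical
                        po2 = mean + b_mother + b_plac + rng.normal(
                            0.0, config.sd_residual_mmhg
                        )
                    rows.append(
                        {
                            "mother_id": mother,
                            "genotype": geno,
                            "placenta_id": placenta,
                            "label": label,
                            "oxygen_percent": float(o),
                            "true_po2_mmhg": po2,
                            "true_t1_s": po2_to_t1(po2, config.calibration),
                            "true_s0": s0,
                            "sigma_g": config.sigma_g,
                        }
                    )
    return pd.DataFrame(rows)


def simulate_records(config: PhantomConfig, seed: int | None = None) -> pd.DataFrame:
    """Fast record-level simulation for statistical Monte-Carlo work.

    Returns one row per placenta x condition with the true PO2/T1/S0 as the
    measured outcome (no imaging chain), preserving the nested variance
    structure the mixed model assumes.  ``seed`` overrides ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    truth = _sample_truth(config, rng)
    out = truth.rename(
        columns={"true_po2_mmhg": "po2_mmhg", "true_t1_s": "t1_s", "true_s0": "s0"}
    )
    return out.drop(columns=["sigma_g"])


# ---------------------------------------------------------------------------
# Image-level phantom


@dataclass
class _Ellipsoid:
    center_mm: np.ndarray      # (3,)
    semiaxes_mm: np.ndarray    # (3,)

    def mask_on(self, grid: GridSpec) -> np.ndarray:
        xs, ys, zs = grid.voxel_centers_world()
        cx, cy, cz = self.center_mm
        ax, ay, az = self.semiaxes_mm
        return (
            ((xs - cx) / ax) ** 2 + ((ys - cy) / ay) ** 2 + ((zs - cz) / az) ** 2
        ) <= 1.0


@dataclass
class StudyBundle:
    """Everything one synthetic study produces."""

    sessions: dict[tuple[str, float], MagnitudeSeries]
    rois: RoiSet
    noise_mask_f19: np.ndarray
    f19_affine: np.ndarray
    design: pd.DataFrame
    truth: pd.DataFrame
    config: PhantomConfig


def _noise_box_bounds(grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """World-mm bounds of the signal-free noise ROI (a corner box)."""
    A = grid.affine()
    lo_ijk = np.array([1.0, 1.0, 1.0])
    hi_ijk = np.array([13.0, 13.0, 5.0])
    lo = A[:3, :3] @ (lo_ijk - 0.5) + A[:3, 3]
    hi = A[:3, :3] @ (hi_ijk - 0.5) + A[:3, 3]
    return np.minimum(lo, hi), np.maximum(lo, hi)


def _box_mask(grid: GridSpec, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    xs, ys, zs = grid.voxel_centers_world()
    return (
        (xs >= lo[0]) & (xs <= hi[0])
        & (ys >= lo[1]) & (ys <= hi[1])
        & (zs >= lo[2]) & (zs <= hi[2])
    )


def _place_ellipsoids(
    n: int, config: PhantomConfig, rng: np.random.Generator
) -> list[_Ellipsoid]:
    """Non-overlapping ellipsoids inside the 19F stack, clear of the noise box."""
    grid = config.f19_grid
    half_fov = np.asarray(grid.shape) * np.asarray(grid.spacing) / 2.0
    box_lo, box_hi = _noise_box_bounds(grid)
    placed: list[_Ellipsoid] = []
    for _ in range(n):
        for _try in range(500):
            semi = np.array(
                [rng.uniform(1.8, 2.7), rng.uniform(1.8, 2.7), rng.uniform(1.8, 2.8)]
            )
            margin = semi + 0.5
            center = np.array(
                [
                    rng.uniform(-half_fov[0] + margin[0], half_fov[0] - margin[0]),
                    rng.uniform(-half_fov[1] + margin[1], half_fov[1] - margin[1]),
                    rng.uniform(-half_fov[2] + margin[2], half_fov[2] - margin[2]),
                ]
            )
            r = semi.max()
            near_box = np.all(center > box_lo - r - 2.0) and np.all(
                center < box_hi + r + 2.0
            )
            if near_box:
                continue
            ok = all(
                np.linalg.norm(center - e.center_mm) > r + e.semiaxes_mm.max() + 1.0
                for e in placed
            )
            if not ok:
                continue
            ell = _Ellipsoid(center, semi)
            if ell.mask_on(grid).sum() >= 12:  # must be resolvable on the coarse grid
                placed.append(ell)
                break
        else:
            raise RuntimeError("could not place non-overlapping placenta ROIs")
    return placed


def generate_study(config: PhantomConfig) -> StudyBundle:
    """Generate a full synthetic study: images, ROIs, design and truth.

    For each mother x oxygen condition a 4-TR magnitude series is produced on
    the 19F grid; placenta ROI labels (and the designated background-noise
    label) are rasterized on the anatomical grid, with the noise ROI also
    rasterized on the 19F grid for native-image noise estimation.
    Deterministic under a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = _sample_truth(config, rng)

    placentas = truth[["mother_id", "genotype", "placenta_id", "label"]].drop_duplicates()
    ellipsoids: dict[int, _Ellipsoid] = {}
    f19_masks: dict[int, np.ndarray] = {}
    anat_labels = np.zeros(config.anat_grid.shape, dtype=np.int16)
    for mother, group in placentas.groupby("mother_id", sort=False):
        # one shared geometry per mother, reused across oxygen conditions
        placed = _place_ellipsoids(len(group), config, rng)
        for (_, row), ell in zip(group.iterrows(), placed):
            lab = int(row["label"])
            ellipsoids[lab] = ell
            f19_masks[lab] = ell.mask_on(config.f19_grid)
            anat_labels[ell.mask_on(config.anat_grid)] = lab

    box_lo, box_hi = _noise_box_bounds(config.f19_grid)
    noise_mask_f19 = _box_mask(config.f19_grid, box_lo, box_hi)
    anat_labels[_box_mask(config.anat_grid, box_lo, box_hi)] = BACKGROUND_LABEL

    label_map = {
        int(r["label"]): (r["mother_id"], r["placenta_id"])
        for _, r in placentas.iterrows()
    }
    rois = RoiSet(
        labels=anat_labels,
        affine=config.anat_grid.affine(),
        label_map=label_map,
        background_label=BACKGROUND_LABEL,
    )

    f19_affine = config.f19_grid.affine()
    tr = np.asarray(config.tr_list_ms, dtype=float)
    sessions: dict[tuple[str, float], MagnitudeSeries] = {}
    design_rows = []
    mothers = placentas[["mother_id", "genotype"]].drop_duplicates()
    for _, mrow in mothers.iterrows():
        mother, geno = mrow["mother_id"], mrow["genotype"]
        for o in config.oxygen_levels:
            sub = truth[(truth["mother_id"] == mother) & (truth["oxygen_percent"] == o)]
            noiseless = np.zeros((tr.size,) + config.f19_grid.shape)
            for _, prow in sub.iterrows():
                mask = f19_masks[int(prow["label"])]
                if config.compartments is None:
                    curve = saturation_recovery_signal(
                        tr, prow["true_s0"], prow["true_t1_s"]
                    )
                else:
                    # maternal pool carries the oximetry signal: its T1 is the
                    # placenta's truth; other pools keep the model's T1s
                    model = dataclasses.replace(
                        config.compartments,
                        t1_s=(prow["true_t1_s"],) + tuple(config.compartments.t1_s[1:]),
                    )
                    curve = mix_compartments(model, tr, s0=prow["true_s0"])
                noiseless[:, mask] = curve[:, None]
            n1 = rng.normal(0.0, config.sigma_g, noiseless.shape)
            n2 = rng.normal(0.0, config.sigma_g, noiseless.shape)
            magnitude = np.hypot(noiseless + n1, n2)
            sessions[(mother, float(o))] = MagnitudeSeries(
                tr_ms=tr.copy(),
                volumes=magnitude,
                affine=f19_affine,
                meta={"nucleus": "19F", "mother_id": mother, "oxygen_percent": float(o),
                      "sigma_g_true": config.sigma_g},
            )
            design_rows.append(
                {"mother_id": mother, "genotype": geno, "oxygen_percent": float(o)}
            )

    design = validate_design_table(pd.DataFrame(design_rows))
    return StudyBundle(
        sessions=sessions,
        rois=rois,
        noise_mask_f19=noise_mask_f19,
        f19_affine=f19_affine,
        design=design,
        truth=truth,
        config=config,
    )
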