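"""Ground-truth-known synthetic SILK datasets and Skyline-like exports.

The generator emulates the statistical structure the analysis assumes: 13
sampling times roughly every 3 h over 36.2 h, a 9 h label window, per-fluid
vertical shifts, I0-proportional weights with normal RIA noise, outlier
contamination, missing points, multi-leucine peptides, and the three
archetype dynamics (comparable fluids, faster CSF, faster plasma). Heavy
intensities are derived from the target RIA and the drawn light intensity so
that the light/heavy ratio stays realistic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import Observation, compute_ria
from .models import MODELS, integrate
from .protocols import InfusionProtocol

__all__ = ["SyntheticDesign", "SyntheticTruth", "ARCHETYPES",
           "generate_protein", "generate_cohort", "DEFAULT_TIMES",
           "write_skyline_csv"]

# 13 collection times, roughly every 3 h, 36.2 h in total
DEFAULT_TIMES = np.array([0.0, 3.0, 6.0, 9.0, 12.0, 15.0, 18.0, 21.0,
                          24.0, 27.0, 30.0, 33.0, 36.2])

# Simplified-model rate sets reproducing the three archetype patterns:
# similar dynamics in both fluids, faster/higher CSF (TTR-like), and faster
# plasma (APOH-like). Chosen so that peak RIAs fall in the observed
# 0.02-0.06 range and single-fluid clearance estimates order accordingly.
ARCHETYPES: dict[str, dict] = {
    "comparable": dict(syn_plasma=0.012, syn_cns=0.03, elim_plasma=0.12,
                       elim_cns=0.12, k_plasma_csf=0.02, k_csf_plasma=0.1,
                       k_cns_csf=0.15, k_csf_cns=0.02),
    "faster_csf": dict(syn_plasma=0.002, syn_cns=0.06, elim_plasma=0.02,
                       elim_cns=0.3, k_plasma_csf=0.003, k_csf_plasma=0.02,
                       k_cns_csf=0.45, k_csf_cns=0.3),
    "faster_plasma": dict(syn_plasma=0.05, syn_cns=0.008, elim_plasma=0.45,
                          elim_cns=0.05, k_plasma_csf=0.03, k_csf_plasma=0.05,
                          k_cns_csf=0.06, k_csf_cns=0.01),
}

_PEPTIDE_ALPHABET = list("ACDEFGHIKMNPQRSTVWY")  # no leucine; L added explicitly


@dataclass
class SyntheticDesign:
    """Study design for synthetic cohorts (defaults emulate the protocol)."""

    times: np.ndarray = field(default_factory=lambda: DEFAULT_TIMES.copy())
    n_proteins: int = 10
    obs_per_fluid: int = 4
    n_leu_choices: tuple = (1, 2, 3)
    n_leu_probs: tuple = (0.5, 0.3, 0.2)
    i0_median: float = 1e5
    i0_sigma: float = 1.0
    noise_precision: dict = field(
        default_factory=lambda: {"plasma": 2.5e5, "csf": 2.5e5})
    shifts: dict = field(
        default_factory=lambda: {"plasma": 0.002, "csf": -0.002})
    obs_shift_sd: float = 0.002      # extra per-observation vertical offset
    outlier_rate: float = 0.05
    missing_rate: float = 0.05
    archetype_mix: dict = field(default_factory=lambda: {
        "comparable": 1 / 3, "faster_csf": 1 / 3, "faster_plasma": 1 / 3})
    defect_rate: float = 0.0         # fraction of proteins given QC defects
    model: str = "three_bc_simplified"

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        if np.any((self.times < 0) | (self.times > 36.2)):
            raise ValueError("times must lie within [0, 36.2]")
        if abs(sum(self.archetype_mix.values()) - 1.0) > 1e-9:
            raise ValueError("archetype mix must sum to 1")
        for v in self.noise_precision.values():
            if v <= 0:
                raise ValueError("noise precisions must be > 0")


@dataclass
class SyntheticTruth:
    """Everything needed to predict the expected analysis outcome."""

    protein_id: str
    model: str
    archetype: str
    rates: dict
    shifts: dict
    obs_offsets: dict        # observation key -> extra vertical offset
    outlier_points: dict     # observation key -> list of point indices
    missing_points: dict     # observation key -> list of point indices
    defects: dict = field(default_factory=dict)  # obs key -> planted defect

    def to_dict(self) -> dict:
        return asdict(self)


def _random_peptide(rng, n_leu: int, length: int = 9) -> str:
    core = rng.choice(_PEPTIDE_ALPHABET, size=length - n_leu)
    seq = list(core) + ["L"] * n_leu
    rng.shuffle(seq)
    return "".join(seq) + "K"


def _i6_from_ria(ria_adj, i0, n_leu):
    """Invert the adjusted RIA for the heavy intensity; clips infeasible
    targets (raw heavy fraction outside [0, 0.9])."""
    rho = np.clip(np.asarray(ria_adj) * n_leu, 0.0, 0.9)
    return rho * np.asarray(i0) / (1.0 - rho)


def generate_protein(rates: dict, design: SyntheticDesign, seed,
                     protein_id: str = "SYN1", archetype: str = "custom",
                     protocol: InfusionProtocol | None = None,
                     ) -> tuple[list, SyntheticTruth]:
    """Simulate all observations of one protein in both fluids.

    RIA targets are the model curves plus the per-fluid shift, a small
    per-observation offset, and heteroscedastic normal noise with variance
    ``1 / (precision * w_i)`` where ``w_i = I0_i / mean(I0)``. Points at
    t = 0 carry noise only (no tracer incorporated). Outliers are uniform
    spikes placed 0.5-2 curve ranges away from the curve so that the
    half-range outlier rule applies to them; missing points are dropped.
    """
    rng = np.random.default_rng(seed)
    protocol = protocol or InfusionProtocol()
    spec = MODELS[design.model]
    vec = [rates[k] for k in spec.rate_names]
    traj = integrate(spec, vec, protocol, design.times, method="expm")
    curves = {"plasma": traj.r_plasma, "csf": traj.r_csf}

    observations = []
    truth = SyntheticTruth(
        protein_id=protein_id, model=design.model, archetype=archetype,
        rates=dict(rates), shifts=dict(design.shifts), obs_offsets={},
        outlier_points={}, missing_points={})
    nt = len(design.times)
    for fluid in ("plasma", "csf"):
        r = curves[fluid]
        rng_range = float(np.max(r) - np.min(r))
        tau = design.noise_precision[fluid]
        for j in range(design.obs_per_fluid):
            n_leu = int(rng.choice(design.n_leu_choices,
                                   p=design.n_leu_probs))
            i0 = rng.lognormal(np.log(design.i0_median), design.i0_sigma, nt)
            w = i0 / np.mean(i0)
            obs_off = float(rng.normal(0.0, design.obs_shift_sd))
            noise = rng.normal(0.0, 1.0 / np.sqrt(tau * w))
            base = np.where(design.times == 0.0, 0.0, r)
            target = base + design.shifts[fluid] + obs_off + noise

            out_idx = np.nonzero((rng.random(nt) < design.outlier_rate)
                                 & (design.times > 0))[0]
            for i in out_idx:
                spike = rng.uniform(0.5, 2.0) * max(rng_range, 0.01)
                target[i] = base[i] + spike * rng.choice([-1.0, 1.0])
            miss_idx = np.nonzero(rng.random(nt) < design.missing_rate)[0]

            i6 = _i6_from_ria(target, i0, n_leu)
            i0_obs, i6_obs = i0.copy(), i6.copy()
            i0_obs[miss_idx] = 0.0
            i6_obs[miss_idx] = 0.0

            obs = Observation(
                protein_id=protein_id, peptide_seq=_random_peptide(rng, n_leu),
                fraction=f"F{j + 1}", charge=int(rng.choice([2, 3])),
                fluid=fluid, n_leu=n_leu, times=design.times.copy(),
                i0=i0_obs, i6=i6_obs)
            observations.append(obs)
            truth.obs_offsets[obs.key] = obs_off
            truth.outlier_points[obs.key] = out_idx.tolist()
            truth.missing_points[obs.key] = miss_idx.tolist()
    return observations, truth


def _plant_defect(obs: Observation, kind: str, rng) -> Observation:
    """Damage an observation so that a specific QC filter must reject it."""
    nt = len(obs.times)
    if kind == "no_leucine":
        obs.peptide_seq = "".join(rng.choice(_PEPTIDE_ALPHABET, size=9)) + "K"
        # n_leu stays >= 1 in the container; the parser recounts from the
        # sequence, which is what the leucine filter sees
    elif kind == "sparse_coverage":
        drop = rng.choice(nt, size=nt - 8, replace=False)  # keep 8 of 13
        obs.i0[drop] = 0.0
        obs.i6[drop] = 0.0
    elif kind == "aberrant_shape":
        # V-shaped RIA series (high, collapsing, rising again): no
        # single-peaked incorporation curve can track it
        down = np.linspace(0.08, 0.0, (nt + 1) // 2)
        up = down[::-1][1:][:nt - len(down)]
        ria = np.concatenate([down, up]) / obs.n_leu
        obs.i6 = _i6_from_ria(ria, np.where(obs.i0 > 0, obs.i0, 1.0), obs.n_leu)
        obs.i6[obs.i0 <= 0] = 0.0
    else:
        raise ValueError(f"unknown defect {kind!r}")
    return obs


def generate_cohort(design: SyntheticDesign, seed, out_dir=None,
                    protocol: InfusionProtocol | None = None):
    """Generate a multi-protein cohort and optional Skyline-like CSV exports.

    Returns ``(observations, truths)``; when ``out_dir`` is given, writes
    ``plasma.csv``, ``csf.csv`` and ``truth.json`` in the export dialect that
    the QC parser reads. A ``defect_rate`` fraction of proteins receives one
    planted QC defect per fluid, labeled in the truth table.
    """
    rng = np.random.default_rng(seed)
    names = list(design.archetype_mix)
    probs = np.array([design.archetype_mix[n] for n in names])
    all_obs, truths = [], []
    n_defective = int(round(design.defect_rate * design.n_proteins))
    defect_kinds = ["no_leucine", "sparse_coverage", "aberrant_shape"]
    for i in range(design.n_proteins):
        arch = str(rng.choice(names, p=probs))
        pid = f"SYNP{i + 1:03d}"
        obs, truth = generate_protein(
            ARCHETYPES[arch], design, seed=rng.integers(2 ** 31),
            protein_id=pid, archetype=arch, protocol=protocol)
        if i < n_defective:
            kind = defect_kinds[i % len(defect_kinds)]
            for fluid in ("plasma", "csf"):
                target = next(o for o in obs if o.fluid == fluid)
                _plant_defect(target, kind, rng)
                truth.defects[target.key] = kind
        all_obs.extend(obs)
        truths.append(truth)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for fluid in ("plasma", "csf"):
            rows = [o for o in all_obs if o.fluid == fluid]
            write_skyline_csv(rows, out_dir / f"{fluid}.csv")
        with open(out_dir / "truth.json", "w") as fh:
            json.dump([t.to_dict() for t in truths], fh, indent=1)
    return all_obs, truths


def write_skyline_csv(observations, path):
    """Write observations as a Skyline-like long-format peak-intensity CSV.

    One row per peptide x fraction x charge x label channel x time point,
    with zero/absent intensities left blank as Skyline does.
    """
    records = []
    for o in observations:
        for label, series in (("light", o.i0), ("heavy", o.i6)):
            for t, v in zip(o.times, series):
                records.append({
                    "Protein": o.protein_id,
                    "Peptide": o.peptide_seq,
                    "Precursor Charge": o.charge,
                    "Isotope Label Type": label,
                    "Fraction": o.fraction,
                    "Time": t,
                    "Total Area": "" if v <= 0 else f"{v:.4f}",
                })
    pd.DataFrame.from_records(records).to_csv(path, index=False)
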