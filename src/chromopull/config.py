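"""Run configuration: every tunable of the pipeline in one YAML document.

``RunConfig`` collects the defaults of all stages — force windows,
detector thresholds, physical constants, generator settings — under one
flat, strictly-validated namespace.  Unknown keys are rejected and a
config round-trips losslessly through YAML, so a run is fully described by
its config file plus a seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Tuple

import yaml

from .fiber import FiberParams
from .wlc import KBT_PN_NM, LAMBDA_DNA_BP, LAMBDA_TEMPLATE_BP, RISE_NM_PER_BP, WLCParams


@dataclass(frozen=True)
class RunConfig:
    # --- DNA mechanics ---
    persistence_nm: float = 50.0
    stretch_pN: float = 1500.0
    rise_nm_per_bp: float = RISE_NM_PER_BP
    kBT_pN_nm: float = KBT_PN_NM
    lambda_bp: int = LAMBDA_DNA_BP
    projection_reference_bp: int = LAMBDA_TEMPLATE_BP

    # --- fiber model ---
    NRL_bp: float = 197.0
    wrap_full_bp: float = 146.0
    wrap_state1_bp: float = 92.0
    wrap_state2_bp: float = 79.0
    stiffness_mode: str = "fiber"

    # --- counting / fitting windows (pN) ---
    count_window_pN: Tuple[float, float] = (8.0, 15.0)
    count_force_cap_pN: float = 10.0
    folded_window_pN: Tuple[float, float] = (0.5, 2.0)
    fit_window_pN: Tuple[float, float] = (0.3, 10.0)
    counting_estimator: str = "median"
    correct_unfolded: bool = True
    rupture_handling: str = "mask"
    init_dG2_kT: float = 4.5

    # --- rupture detection ---
    rupture_threshold_bp: float = 200.0
    rupture_join_gap_points: int = 5
    rupture_force_window_pN: Tuple[float, float] = (1.0, 15.0)
    rupture_class_cutoff_pN: float = 8.0
    median_filter_points: int = 15
    rupture_fit_span_points: int = 60
    dR_threshold_um: float = 0.1
    dR_avg_points: int = 5

    # --- cohort statistics ---
    pairwise_test: str = "welch"

    # --- synthetic data ---
    sim_n_octamers: int = 125
    sim_folded_fraction: float = 0.39
    sim_placement_mode: str = "clustered"
    sim_cluster_size_range: Tuple[int, int] = (3, 10)
    sim_nfr_range_bp: Tuple[float, float] = (100.0, 300.0)
    sim_k_fiber: float = 0.25
    sim_dG1_kT: float = 20.0
    sim_dG2_kT: float = 4.5
    sim_last_turn_mean_pN: float = 20.0
    sim_last_turn_sd_pN: float = 5.0
    sim_last_turn_min_pN: float = 10.0
    sim_loop_force_range_pN: Tuple[float, float] = (1.0, 15.0)
    sim_loop_size_range_bp: Tuple[float, float] = (250.0, 10000.0)
    sim_noise_nm: float = 10.0
    sim_xy_noise_um: float = 0.02
    sim_sample_rate_hz: float = 60.0
    sim_ramp_pN: Tuple[float, float] = (0.3, 40.0)
    sim_ramp_duration_s: float = 40.0

    seed: int = 0

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name: f for f in fields(cls)}
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for k, v in d.items():
            if isinstance(v, list):
                v = tuple(v)
            kwargs[k] = v
        return cls(**kwargs)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        p = Path(source)
        text = p.read_text(encoding="utf-8") if p.exists() else str(source)
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)

    def config_hash(self) -> str:
        """Short SHA-256 of the canonical YAML form, for run logging."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    def replace(self, **changes) -> "RunConfig":
        return dataclasses.replace(self, **changes)

    # ------------------------------------------------------------------
    def wlc_params(self, contour_bp: float) -> WLCParams:
        return WLCParams(
            contour_bp=contour_bp,
            persistence_nm=self.persistence_nm,
            stretch_pN=self.stretch_pN,
            rise_nm_per_bp=self.rise_nm_per_bp,
            kBT_pN_nm=self.kBT_pN_nm,
        )

    def fiber_params(self, N_total: int, N_folded: int, L_DNA_bp: float,
                     k_fiber: float, dG1_kT: float, dG2_kT: float) -> FiberParams:
        return FiberParams(
            k_fiber=k_fiber, dG1_kT=dG1_kT, dG2_kT=dG2_kT,
            N_total=N_total, N_folded=N_folded, NRL_bp=self.NRL_bp,
            L_DNA_bp=L_DNA_bp, wrap_full_bp=self.wrap_full_bp,
            wrap_state1_bp=self.wrap_state1_bp,
            wrap_state2_bp=self.wrap_state2_bp,
            stiffness_mode=self.stiffness_mode,
        )
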