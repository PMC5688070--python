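"""Pipeline configuration.

Every empirical threshold of the analysis is exposed here with its published
default: the 5-40 Hz band-pass, the 50 mg / 28 mg^2 gross artifact gates, the
S1/S2 envelope morphology windows, the anchor-point acceptance rules, the
sinc-refinement geometry and the two congruency tolerances.  Values are in
milliseconds or milli-g unless the field name says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields, is_dataclass
from typing import Tuple

import yaml


class ConfigurationError(ValueError):
    """Raised for inconsistent or unusable configuration values."""


@dataclass
class FilterConfig:
    low_hz: float = 5.0
    high_hz: float = 40.0
    order: int = 2          # per pass; forward-reverse doubles the effective order


@dataclass
class ScreenConfig:
    p2p_mg: float = 50.0
    var_mg2: float = 28.0
    s1_window_ms: Tuple[float, float] = (10.0, 160.0)
    s2_window_ms: Tuple[float, float] = (300.0, 480.0)
    population_variance: bool = True


@dataclass
class EnvelopeConfig:
    taps: int = 31


@dataclass
class TeConfig:
    method: str = "tangent"            # "tangent" | "trapezium"
    plausible_ms: Tuple[float, float] = (150.0, 500.0)


@dataclass
class QConfig:
    window_ms: Tuple[float, float] = (8.0, 80.0)   # search [R-80, R-8]


@dataclass
class AnchorConfig:
    icp_window_ms: Tuple[float, float] = (25.0, 75.0)   # S1si
    icp_ref_tol_ms: float = 30.0
    s2si_half_ms: float = 30.0                           # S2si = Te +/- 30 ms
    irp_d_min_mg: float = 7.0
    irp_ref_tol_ms: float = 20.0
    irp_history_beats: int = 20
    lookahead_rri_tol_ms: float = 100.0
    lookahead_irp_tol_ms: float = 20.0


@dataclass
class FpConfig:
    constrain_s1si: bool = False   # additionally confine MC/AO peaks to S1si
    ao_amp_frac: float = 0.7
    ao_window_ms: float = 50.0
    mc_window_ms: float = 50.0
    ac_gap_ms: Tuple[float, float] = (10.0, 40.0)
    mo_gap_ms: Tuple[float, float] = (10.0, 30.0)


@dataclass
class HiresConfig:
    window_samples: int = 101
    grid_ms: float = 1.0
    halfspan_ms: float = 5.0       # 10 ms re-estimation window centred on CFTP


@dataclass
class InflectionConfig:
    slope_frac: float = 0.3            # shoulder slope < frac * max slope of segment
    expected_halfwidth_ms: float = 10.0
    history_beats: int = 5


@dataclass
class CongruencyConfig:
    fp_tol_systolic_ms: float = 10.0   # MC, AO
    fp_tol_diastolic_ms: float = 20.0  # AC, MO
    cti_tol_pep_ms: float = 10.0
    cti_tol_other_ms: float = 20.0
    window_beats: int = 5
    iterate: bool = False              # single-pass by default


@dataclass
class PipelineConfig:
    filter: FilterConfig = field(default_factory=FilterConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    envelope: EnvelopeConfig = field(default_factory=EnvelopeConfig)
    te: TeConfig = field(default_factory=TeConfig)
    q: QConfig = field(default_factory=QConfig)
    anchor: AnchorConfig = field(default_factory=AnchorConfig)
    fp: FpConfig = field(default_factory=FpConfig)
    hires: HiresConfig = field(default_factory=HiresConfig)
    inflection: InflectionConfig = field(default_factory=InflectionConfig)
    congruency: CongruencyConfig = field(default_factory=CongruencyConfig)
    edge_guard_s: float = 0.5          # filter warm-up excluded from beat windows

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls()
        for f in fields(cls):
            if f.name not in d:
                continue
            cur = getattr(cfg, f.name)
            val = d[f.name]
            if is_dataclass(cur) and isinstance(val, dict):
                for k, v in val.items():
                    if not hasattr(cur, k):
                        raise ConfigurationError(f"unknown config key {f.name}.{k}")
                    if isinstance(getattr(cur, k), tuple):
                        v = tuple(v)
                    setattr(cur, k, v)
            else:
                setattr(cfg, f.name, val)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)
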