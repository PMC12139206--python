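"""Pipeline configuration.

Every threshold used by the analysis stages lives here so that a run is fully
described by one object (plus the RNG seed).  Defaults follow the published
processing choices for bluefin-tuna archival tags: a 2-s static window for
gravity separation, 10-s VeDBA smoothing, a 10 m / 20 s first-dive definition,
a deployment-wide 99th-percentile fast-start threshold, a 1 %-of-day
inactivity cutoff, and a 10,000-shuffle / 30-day / 5th-percentile
rank-permutation similarity test with the altered-week decision taken over
post-release days 1-7 at a mean-rank cutoff of 15.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class PipelineConfig:
    # acceleration processing
    static_window_s: float = 2.0          # running-mean window for static split (fs >= 5 Hz)
    static_window_lowres_s: float = 25.0  # used when fs < 5 Hz (2 s would hold < 1 sample)
    vedba_smooth_s: float = 10.0
    lowres_fs: float = 0.2                # common down-sampled rate (MiniPAT-style)

    # tailbeat wavelet analysis
    tailbeat_min_fs: float = 5.0          # lateral tailbeat signal is lost below 5 Hz
    cwt_min_period_s: float = 0.125
    cwt_max_period_s: float = 2.0
    cwt_n_periods: int = 32
    cwt_omega0: float = 6.0               # Morlet centre frequency
    dsf_noise_floor_g: float = 0.01       # intervals with weaker ridges report no DSF

    # plateau (stabilisation) detection
    plateau_frac: float = 0.05            # plateau when residual burst <= 5 % of amplitude
    plateau_horizon_h: int = 24

    # events
    dive_depth_threshold_m: float = 10.0
    dive_min_duration_s: float = 20.0
    depth_smooth_s: float = 10.0
    depth_temp_coeff_m_per_degc: float = 0.0   # temperature correction, 0 = identity
    depth_temp_ref_degc: float = 15.0
    fast_start_quantile: float = 0.99
    inactive_day_frac: float = 0.01       # < 1 % of day in fast starts = inactive

    # diel / similarity analysis
    n_permutations: int = 10000
    block_days: int = 30
    post_window_days: int = 7
    rank_mean_cutoff: float = 15.0
    rank_mean_inclusive: bool = True      # "lower half" reading: mean rank <= 15
    flag_quantile: float = 0.05
    flag_inclusive: bool = True           # observed rank <= empirical 5th percentile
    flag_on_ranks: bool = True            # compare ranks, not raw similarity values
    diel_window_days: int = 7
    diel_min_days: int = 3
    min_common_hours: int = 3
    alpha: float = 0.05
    day_start_hour: float = 6.0           # fixed UTC day/night bounds when no solar input
    day_end_hour: float = 18.0

    # movement
    hmm_n_states: int = 2
    hmm_n_restarts: int = 25
    hmm_min_days: int = 30
    earth_radius_km: float = 6371.0

    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "static_window_s", "static_window_lowres_s", "vedba_smooth_s",
            "lowres_fs", "tailbeat_min_fs", "cwt_min_period_s",
            "cwt_max_period_s", "dive_depth_threshold_m", "dive_min_duration_s",
            "depth_smooth_s", "n_permutations", "block_days",
            "post_window_days", "rank_mean_cutoff", "diel_window_days",
            "diel_min_days", "hmm_n_states", "hmm_n_restarts",
            "earth_radius_km",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("fast_start_quantile", "inactive_day_frac",
                     "flag_quantile", "alpha"):
            q = getattr(self, name)
            if not 0.0 < q < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.cwt_min_period_s >= self.cwt_max_period_s:
            raise ValueError("cwt_min_period_s must be < cwt_max_period_s")

    def to_dict(self) -> dict:
        return asdict(self)
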