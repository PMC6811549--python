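"""Genotype presets: the distributions the synthetic cohorts are drawn from.

Group-mean anchors (uEPSC amplitude, silent-spine fraction, HCN midpoint,
multi-innervated-spine incidence, mEPSC rates/amplitudes, morphology)
are reference group values for wild-type and Fmr1-knockout layer-4
stellate cells at the end of the second postnatal week.  Unanchored
biophysical knobs (leak, maximal HCN conductance, kinetics, dendritic
coupling, per-spine conductance scales) were calibrated once so that the
simulated protocols land near those anchor values; they are
frozen here and documented in the methods note.

Dispersion families are log-normal for positive quantities unless noted;
``*_cv`` values are coefficients of variation on the natural scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


# measured uEPSC amplitude (pA) per nS of AMPA conductance under the
# two-compartment voltage-clamp uncaging protocol (calibration constant)
PA_PER_NS_AMPA = 24.5
# measured NMDA/AMPA amplitude ratio per unit conductance ratio
MEASURED_RATIO_PER_G_RATIO = 0.76


@dataclass
class GenotypePreset:
    name: str = "WT"

    # --- intrinsic membrane (means; per-cell draws jitter these) -------
    g_leak_ns: float = 3.0
    g_leak_cv: float = 0.08
    cm_pf: float = 150.0
    cm_cv: float = 0.07
    g_hcn_ns: float = 1.9
    g_hcn_cv: float = 0.10
    hcn_v12_mv: float = -86.0
    hcn_v12_sd: float = 1.5
    hcn_k_mv: float = 10.0

    # --- dendrite (two-compartment summation regime) -------------------
    g_c_ns: float = 2.5
    g_leak_dend_ns: float = 0.3
    cm_dend_pf: float = 10.0

    # --- sequential single-spine uncaging (voltage clamp) ---------------
    uepsc_mean_pa: float = 6.9       # measured group mean incl. MIS spines
    uepsc_cv: float = 0.45           # spine-to-spine dispersion
    animal_log_sd: float = 0.10      # animal-level random effect (log scale)
    litter_log_sd: float = 0.05
    silent_fraction: float = 0.064
    nmda_ampa_ratio: float = 0.97    # measured spine-average target
    nmda_ratio_cv: float = 0.25
    mis_fraction: float = 0.072      # P(spine has >1 contact)
    spines_per_cell: int = 8

    # --- near-simultaneous multi-spine uncaging (current clamp) ---------
    multi_g_ampa_ns: float = 3.0
    multi_g_ampa_cv: float = 0.20
    multi_nmda_g_ratio: float = 0.40  # conductance ratio, WT scale
    n_multi_spines: int = 10

    # --- thalamocortical train -----------------------------------------
    tca_g_ns: float = 10.5
    tca_trial_cv: float = 0.10
    background_rate_hz: float = 2.0   # spontaneous synaptic bombardment
    background_g_ns: float = 1.5
    background_g_cv: float = 0.40

    # --- mEPSCs (direct synthesis at the recording stage) ----------------
    mepsc_ampa_rate_hz: float = 3.9
    mepsc_ampa_amp_pa: float = 13.1
    mepsc_nmda_rate_hz: float = 1.7
    mepsc_nmda_amp_pa: float = 16.9
    mepsc_amp_cv: float = 0.30

    # --- recording noise -------------------------------------------------
    noise_vc_pa: float = 2.0
    noise_cc_mv: float = 0.2

    # --- morphology / ultrastructure -------------------------------------
    head_width_um: float = 0.48
    head_width_cv: float = 0.25
    neck_length_um: float = 1.36
    neck_length_cv: float = 0.40
    spine_density_per_10um: float = 6.8
    morph_animal_log_sd: float = 0.10
    spines_per_dendrite: float = 4.4
    dendrites_per_animal: tuple[int, int] = (6, 11)

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def nmda_g_ratio(self) -> float:
        """Conductance-level NMDA/AMPA ratio for the sequential protocol."""
        return self.nmda_ampa_ratio / MEASURED_RATIO_PER_G_RATIO


# The knockout preset differs in its anchors: larger uEPSCs,
# ~3x silent spines, ~3x MIS, hyperpolarised HCN midpoint, elevated
# NMDA/AMPA ratio, higher NMDAR mEPSC frequency, denser spontaneous
# activity; the channel complement (g_hcn_max) is unchanged.
WT = GenotypePreset()
KO = GenotypePreset(
    name="KO",
    hcn_v12_mv=-92.0,
    uepsc_mean_pa=9.8,
    silent_fraction=0.176,
    nmda_ampa_ratio=1.26,
    mis_fraction=0.205,
    mepsc_ampa_rate_hz=4.9,
    mepsc_ampa_amp_pa=12.7,
    mepsc_nmda_rate_hz=2.6,
    mepsc_nmda_amp_pa=14.4,
    multi_nmda_g_ratio=0.52,   # 1.3x the WT conductance ratio
    background_rate_hz=10.0,
    head_width_um=0.48,
    neck_length_um=1.27,
    spine_density_per_10um=6.1,
)

PRESETS = {"WT": WT, "KO": KO}
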