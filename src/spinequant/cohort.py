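"""Synthetic cohort generation: whole cells with every protocol's sweeps
and known ground truth, under genotype presets.

Each cell draws its biophysics and synapse population from the preset
distributions (with animal- and litter-level random effects inducing the
nesting the group statistics rely on), then simulates the requested
protocols.  Ground truth (parameters, spine table, true event times) is
stored on the cell record for recovery tests.
"""

from __future__ import annotations

import numpy as np

from .data import Sweep, CellRecord, Cohort
from .mepsc import EventTemplate, DEFAULT_NEG, DEFAULT_POS
from .presets import GenotypePreset, PA_PER_NS_AMPA, WT, KO
from .simulate import (NeuronParams, SynapseSpec, StimulusSpec, simulate,
                       holding_bias_for)

PROTOCOLS = ("steps", "sag_steps", "chirp", "ih_vsteps",
             "uncage_seq", "uncage_multi", "tca_train", "mepsc")


def _lognormal(rng, mean, cv):
    if cv <= 0:
        return mean
    sigma = np.sqrt(np.log(1.0 + cv * cv))
    mu = np.log(mean) - 0.5 * sigma * sigma
    return float(rng.lognormal(mu, sigma))


def draw_neuron_params(preset: GenotypePreset, rng) -> NeuronParams:
    return NeuronParams(
        cm=_lognormal(rng, preset.cm_pf, preset.cm_cv),
        g_leak=_lognormal(rng, preset.g_leak_ns, preset.g_leak_cv),
        g_hcn_max=_lognormal(rng, preset.g_hcn_ns, preset.g_hcn_cv),
        hcn_v12=float(rng.normal(preset.hcn_v12_mv, preset.hcn_v12_sd)),
        hcn_k=preset.hcn_k_mv,
        compartments=2,
        g_c=preset.g_c_ns,
        g_leak_dend=preset.g_leak_dend_ns,
        cm_dend=preset.cm_dend_pf,
    )


def draw_spines(preset: GenotypePreset, rng, amp_factor: float = 1.0
                ) -> list[dict]:
    """Sequential-protocol spine table: conductances, contacts, silent flag."""
    g0 = (preset.uepsc_mean_pa * amp_factor
          / PA_PER_NS_AMPA / (1.0 + preset.mis_fraction))
    spines = []
    for i in range(preset.spines_per_cell):
        silent = bool(rng.random() < preset.silent_fraction)
        contacts = 2 if rng.random() < preset.mis_fraction else 1
        g_ampa = 0.0 if silent else _lognormal(rng, g0, preset.uepsc_cv)
        ratio = _lognormal(rng, preset.nmda_g_ratio, preset.nmda_ratio_cv)
        g_ref = g_ampa if not silent else _lognormal(rng, g0, preset.uepsc_cv)
        spines.append(dict(
            spine_id=f"sp{i}", silent=silent, n_contacts=contacts,
            g_ampa=g_ampa, g_nmda=ratio * g_ref,
            distance_um=float(rng.uniform(50.0, 100.0))))
    return spines


def _spine_specs(spines: list[dict]) -> list[SynapseSpec]:
    return [SynapseSpec(spine_id=s["spine_id"], g_ampa=s["g_ampa"],
                        g_nmda=s["g_nmda"], n_contacts=s["n_contacts"])
            for s in spines]


# ---------------------------------------------------------------------------
# per-protocol sweep generation
# ---------------------------------------------------------------------------

def _gen_steps(params, preset, rng):
    amps = np.arange(-125.0, 126.0, 25.0)
    amps = amps[amps != 0]
    return simulate(params, [], StimulusSpec.step_family(list(amps)),
                    seed=int(rng.integers(2**31)), noise_sd=preset.noise_cc_mv)


def _gen_sag_steps(params, preset, rng):
    bias = holding_bias_for(params, -60.0)
    amps = list(np.arange(-125.0, -24.0, 25.0))
    return simulate(params, [],
                    StimulusSpec.step_family(amps, holding_pa=bias),
                    seed=int(rng.integers(2**31)), noise_sd=preset.noise_cc_mv)


def _gen_chirp(params, preset, rng):
    return simulate(params, [], StimulusSpec.chirp(),
                    seed=int(rng.integers(2**31)), noise_sd=preset.noise_cc_mv)


def _gen_ih_vsteps(params, preset, rng):
    return simulate(params, [], StimulusSpec.vstep_family(),
                    mode="voltage_clamp",
                    seed=int(rng.integers(2**31)), noise_sd=preset.noise_vc_pa)


def _gen_uncage_seq(params, preset, spines, rng, n_reps=3):
    """One short voltage-clamp sweep per spine, repetition and holding."""
    specs = _spine_specs(spines)
    groups: dict[str, list[Sweep]] = {"uncage_seq_-70": [], "uncage_seq_+40": []}
    for holding, key in ((-70.0, "uncage_seq_-70"), (40.0, "uncage_seq_+40")):
        for i in range(len(specs)):
            for _ in range(n_reps):
                sw = simulate(params, specs,
                              StimulusSpec.uncaging([(i, 0.1)], 0.35,
                                                    holding=holding),
                              mode="voltage_clamp",
                              seed=int(rng.integers(2**31)),
                              noise_sd=preset.noise_vc_pa)[0]
                groups[key].append(sw)
    return groups


def _gen_uncage_multi(params, preset, rng):
    """Single-spine uEPSPs then cumulative near-simultaneous ensembles."""
    n = preset.n_multi_spines
    silent = rng.random(n) < preset.silent_fraction
    g = np.array([0.0 if s else _lognormal(rng, preset.multi_g_ampa_ns,
                                           preset.multi_g_ampa_cv)
                  for s in silent])
    gn = np.array([preset.multi_nmda_g_ratio
                   * (_lognormal(rng, preset.multi_g_ampa_ns,
                                 preset.multi_g_ampa_cv) if s else g[i])
                   for i, s in enumerate(silent)])
    specs = [SynapseSpec(spine_id=f"m{i}", g_ampa=float(g[i]),
                         g_nmda=float(gn[i])) for i in range(n)]
    bias = holding_bias_for(params, -60.0)
    singles = []
    for i in range(n):
        singles.append(simulate(params, specs,
                                StimulusSpec.uncaging([(i, 0.1)], 0.5,
                                                      holding=bias),
                                seed=int(rng.integers(2**31)),
                                noise_sd=preset.noise_cc_mv)[0])
    ensembles = []
    for count in range(1, n + 1):
        sched = [(i, 0.1 + 0.0005 * i) for i in range(count)]
        sw = simulate(params, specs,
                      StimulusSpec.uncaging(sched, 0.6, holding=bias),
                      seed=int(rng.integers(2**31)),
                      noise_sd=preset.noise_cc_mv)[0]
        sw.meta["count"] = count
        ensembles.append(sw)
    truth = dict(silent=[bool(s) for s in silent],
                 g_ampa=[float(x) for x in g], g_nmda=[float(x) for x in gn])
    return {"uncage_multi_single": singles, "uncage_multi": ensembles}, truth


def _gen_tca_train(params, preset, rng, freqs=(5.0, 10.0), n_trials=10):
    groups: dict[str, list[Sweep]] = {}
    for freq in freqs:
        key = f"tca_train_{freq:g}"
        dur = 0.2 + 5 / freq + 0.3
        sweeps = []
        for _ in range(n_trials):
            g = preset.tca_g_ns * np.exp(
                rng.normal(0.0, preset.tca_trial_cv))
            specs = [SynapseSpec(spine_id="tca", g_ampa=g,
                                 g_nmda=g * preset.multi_nmda_g_ratio)]
            sched = [(0, 0.2 + j / freq) for j in range(5)]
            n_bg = rng.poisson(preset.background_rate_hz * dur)
            for b in range(n_bg):
                gb = _lognormal(rng, preset.background_g_ns,
                                preset.background_g_cv)
                specs.append(SynapseSpec(
                    spine_id=f"bg{b}", g_ampa=gb,
                    g_nmda=gb * preset.multi_nmda_g_ratio))
                sched.append((len(specs) - 1,
                              float(rng.uniform(0.0, dur - 0.05))))
            sw = simulate(params, specs, StimulusSpec.uncaging(sched, dur),
                          seed=int(rng.integers(2**31)),
                          noise_sd=preset.noise_cc_mv)[0]
            # relabel train pulses for the spike-probability window
            sw.markers = [("stim", t) if lab == "uncage:tca" else (lab, t)
                          for lab, t in sw.markers]
            sweeps.append(sw)
        groups[key] = sweeps
    return groups


def synth_mepsc_sweep(rate_hz: float, amp_mean_pa: float, amp_cv: float,
                      duration_s: float, holding_mv: float,
                      noise_sd: float, rng,
                      template: EventTemplate | None = None,
                      fs_hz: float = 20_000.0) -> Sweep:
    """Direct synthesis of a miniature-EPSC voltage-clamp recording:
    Poisson event train, log-normal amplitudes, template kinetics,
    additive Gaussian noise.  True onset times go into the markers."""
    if template is None:
        template = DEFAULT_NEG if holding_mv < 0 else DEFAULT_POS
    n = int(round(duration_s * fs_hz))
    dt = 1.0 / fs_hz
    y = rng.normal(0.0, noise_sd, n)
    kernel = template.waveform(dt)
    n_ev = rng.poisson(rate_hz * duration_s)
    times = np.sort(rng.uniform(0.0, duration_s - len(kernel) * dt, n_ev))
    markers = []
    for t in times:
        amp = _lognormal(rng, amp_mean_pa, amp_cv)
        i0 = int(round(t / dt))
        seg = kernel[:n - i0]
        y[i0:i0 + len(seg)] += amp * seg
        markers.append(("event", float(t)))
    return Sweep(dt=dt, samples=y, stimulus=np.full(n, holding_mv),
                 mode="voltage_clamp", markers=markers, holding=holding_mv)


def _gen_mepsc(preset, rng, duration_s=60.0):
    neg = synth_mepsc_sweep(preset.mepsc_ampa_rate_hz,
                            preset.mepsc_ampa_amp_pa, preset.mepsc_amp_cv,
                            duration_s, -70.0, preset.noise_vc_pa, rng)
    pos = synth_mepsc_sweep(preset.mepsc_nmda_rate_hz,
                            preset.mepsc_nmda_amp_pa, preset.mepsc_amp_cv,
                            duration_s, 40.0, preset.noise_vc_pa, rng)
    return {"mepsc_-70": [neg], "mepsc_+40": [pos]}


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def generate_cell(cell_id: str, genotype: str, animal_id: str,
                  litter_id: str, slice_id: str,
                  preset: GenotypePreset, rng,
                  protocols=PROTOCOLS,
                  amp_factor: float = 1.0,
                  mepsc_duration_s: float = 60.0) -> CellRecord:
    params = draw_neuron_params(preset, rng)
    cell = CellRecord(cell_id=cell_id, genotype=genotype,
                      animal_id=animal_id, litter_id=litter_id,
                      slice_id=slice_id)
    spines = draw_spines(preset, rng, amp_factor)
    truth = dict(params=params.__dict__.copy(), spines=spines,
                 preset=preset.name, amp_factor=amp_factor)
    if "steps" in protocols:
        cell.sweeps["steps"] = _gen_steps(params, preset, rng)
    if "sag_steps" in protocols:
        cell.sweeps["sag_steps"] = _gen_sag_steps(params, preset, rng)
    if "chirp" in protocols:
        cell.sweeps["chirp"] = _gen_chirp(params, preset, rng)
    if "ih_vsteps" in protocols:
        cell.sweeps["ih_vsteps"] = _gen_ih_vsteps(params, preset, rng)
    if "uncage_seq" in protocols:
        cell.sweeps.update(_gen_uncage_seq(params, preset, spines, rng))
    if "uncage_multi" in protocols:
        groups, mtruth = _gen_uncage_multi(params, preset, rng)
        cell.sweeps.update(groups)
        truth["multi"] = mtruth
    if "tca_train" in protocols:
        cell.sweeps.update(_gen_tca_train(params, preset, rng))
    if "mepsc" in protocols:
        cell.sweeps.update(_gen_mepsc(preset, rng, mepsc_duration_s))
    cell.qc = dict(holding_current_pa=float(rng.normal(40.0, 20.0)),
                   membrane_potential_mv=float(rng.normal(-62.0, 2.0)),
                   series_resistance_mohm=float(rng.uniform(8.0, 20.0)),
                   series_resistance_start_mohm=10.0,
                   series_resistance_end_mohm=float(rng.uniform(10.0, 11.0)))
    cell.ground_truth = truth
    return cell


def generate_cohort(preset_wt: GenotypePreset = WT,
                    preset_ko: GenotypePreset = KO,
                    n_animals: int = 3,
                    cells_per_animal: int = 2,
                    protocols=PROTOCOLS,
                    seed: int = 0,
                    mepsc_duration_s: float = 60.0) -> Cohort:
    """Generate a two-genotype cohort with litter/animal/slice nesting.

    ``n_animals`` is per genotype (>= 2 required for the hierarchical
    statistics); each litter contributes one animal of each genotype,
    matching the heterozygous-cross breeding design.
    """
    if n_animals < 2:
        raise ValueError("need >= 2 animals per genotype")
    rng = np.random.default_rng(seed)
    cells = []
    for a in range(n_animals):
        litter = f"L{a + 1}"
        for preset in (preset_wt, preset_ko):
            geno = preset.name
            animal = f"{geno}-A{a + 1}"
            amp_factor = float(np.exp(rng.normal(0.0, preset.animal_log_sd)))
            for c in range(cells_per_animal):
                slice_id = f"{animal}-S{c // 2 + 1}"
                cell = generate_cell(
                    f"{animal}-C{c + 1}", geno, animal, litter, slice_id,
                    preset, rng, protocols=protocols, amp_factor=amp_factor,
                    mepsc_duration_s=mepsc_duration_s)
                cells.append(cell)
    return Cohort(cells=cells,
                  provenance=dict(seed=seed, presets=[preset_wt.name,
                                                      preset_ko.name],
                                  protocols=list(protocols),
                                  n_animals=n_animals,
                                  cells_per_animal=cells_per_animal))


# ---------------------------------------------------------------------------
# morphology and ultrastructure tables
# ---------------------------------------------------------------------------

def generate_morphology(preset: GenotypePreset, n_animals: int, seed: int = 0,
                        dendrite_um: float = 60.0):
    """Spine-morphology table (one row per spine) with per-animal effects.

    Spine counts are Poisson at the preset density over the sampled
    dendritic length, so the per-animal density summary recovers the
    preset value."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for a in range(n_animals):
        animal = f"{preset.name}-M{a + 1}"
        f_a = np.exp(rng.normal(0.0, preset.morph_animal_log_sd))
        n_sp = max(int(rng.poisson(preset.spine_density_per_10um
                                   * dendrite_um / 10.0)), 1)
        for i in range(n_sp):
            rows.append(dict(
                spine_id=f"{animal}-sp{i}", animal_id=animal,
                genotype=preset.name,
                head_width_um=_lognormal(rng, preset.head_width_um * f_a,
                                         preset.head_width_cv),
                neck_length_um=_lognormal(rng, preset.neck_length_um * f_a,
                                          preset.neck_length_cv),
                dendrite_um=dendrite_um))
    return pd.DataFrame(rows)


def generate_ultrastructure(preset: GenotypePreset, n_animals: int,
                            seed: int = 0):
    """Per-dendrite spine and multi-innervated-spine counts (one row per
    reconstructed dendrite), mirroring the serial-EM sampling design."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    lo, hi = preset.dendrites_per_animal
    rows = []
    for a in range(n_animals):
        animal = f"{preset.name}-EM{a + 1}"
        for d in range(int(rng.integers(lo, hi + 1))):
            n_spines = max(int(rng.poisson(preset.spines_per_dendrite)), 1)
            n_mis = int(rng.binomial(n_spines, preset.mis_fraction))
            rows.append(dict(animal_id=animal, genotype=preset.name,
                             dendrite_id=f"{animal}-d{d}",
                             n_spines=n_spines, n_mis=n_mis))
    return pd.DataFrame(rows)
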