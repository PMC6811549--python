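"""Config-driven end-to-end orchestration: simulate -> extract -> compare.

Each stage is a pure function from a cohort to a feature table
(pandas DataFrame); ``run_pipeline`` chains them, writes CSV/JSON
outputs, and serialises its config into the bundle for provenance.
Identical config + seed give byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import intrinsic, ih, uncaging, mepsc, structure, stats
from .data import Cohort
from .io import write_cohort, QCThresholds, reject_cell
from .presets import WT, KO

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 0
    n_animals: int = 3
    cells_per_animal: int = 2
    protocols: tuple = cohort_mod.PROTOCOLS
    mepsc_duration_s: float = 60.0
    output_dir: str = "results"
    qc: QCThresholds = field(default_factory=QCThresholds)
    morphology_animals: int = 3
    ultrastructure_animals: tuple[int, int] = (3, 7)  # WT, KO

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml
            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        qc = raw.pop("qc", None)
        cfg = cls(**raw)
        if qc:
            cfg.qc = QCThresholds(**qc)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["protocols"] = list(self.protocols)
        return d


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_intrinsic(cohort: Cohort) -> pd.DataFrame:
    rows = []
    for cell in cohort:
        prof = intrinsic.intrinsic_profile(
            cell.protocol("steps"),
            chirp_sweep=(cell.protocol("chirp") or [None])[0],
            sag_sweeps=cell.protocol("sag_steps") or None)
        rows.append(dict(cell_id=cell.cell_id, genotype=cell.genotype,
                         animal_id=cell.animal_id, litter_id=cell.litter_id,
                         slice_id=cell.slice_id,
                         r_input_mohm=prof.r_input_mohm,
                         rheobase_pa=prof.rheobase_pa,
                         sag_pct=prof.sag_pct,
                         rebound_slope=prof.rebound_slope,
                         f_res_hz=prof.f_res_hz, q_factor=prof.q_factor))
    return pd.DataFrame(rows)


def stage_ih(cohort: Cohort) -> pd.DataFrame:
    rows = []
    for cell in cohort:
        sweeps = cell.protocol("ih_vsteps")
        if not sweeps:
            continue
        curve = ih.extract_ih(sweeps)
        try:
            fit = ih.fit_activation(curve.step_voltages, curve.ih_amps)
            v12, k, imax = fit.v12, fit.k, fit.i_max
        except RuntimeError:
            v12 = k = imax = np.nan
        rows.append(dict(cell_id=cell.cell_id, genotype=cell.genotype,
                         animal_id=cell.animal_id, litter_id=cell.litter_id,
                         slice_id=cell.slice_id,
                         v12_mv=v12, k_mv=k, g_max=imax,
                         ih_at_deepest_pa=float(curve.ih_amps[-1]),
                         flags=";".join(curve.flags)))
    return pd.DataFrame(rows)


def stage_uncage_seq(cohort: Cohort) -> pd.DataFrame:
    """Spine-level AMPA/NMDA amplitudes and silent calls from the
    sequential uncaging sweeps (repetitions averaged before measuring)."""
    rows = []
    for cell in cohort:
        neg = cell.protocol("uncage_seq_-70")
        pos = cell.protocol("uncage_seq_+40")
        if not neg:
            continue

        def by_spine(sweeps):
            d: dict[str, list] = {}
            for sw in sweeps:
                for lab, t in sw.markers:
                    if lab.startswith("uncage:"):
                        d.setdefault(lab.split(":", 1)[1], []).append((sw, t))
            return d

        neg_d, pos_d = by_spine(neg), by_spine(pos)
        for spine_id, reps in neg_d.items():
            t0 = reps[0][1]
            ampa = uncaging.measure_uepsc_averaged(
                [r[0] for r in reps], t0, receptor="ampa")
            nmda = None
            if spine_id in pos_d:
                preps = pos_d[spine_id]
                nmda = uncaging.measure_uepsc_averaged(
                    [r[0] for r in preps], preps[0][1], receptor="nmda")
            _, base_sd = uncaging.baseline_stats(reps[0][0], t0)
            n_rep = len(reps)
            sd_eff = base_sd / np.sqrt(n_rep)
            call = uncaging.classify_spine(ampa, nmda if nmda is not None
                                           else 0.0, sd_eff)
            truth = {s["spine_id"]: s for s in
                     cell.ground_truth.get("spines", [])}
            rows.append(dict(cell_id=cell.cell_id, genotype=cell.genotype,
                             animal_id=cell.animal_id,
                             litter_id=cell.litter_id,
                             slice_id=cell.slice_id, spine_id=spine_id,
                             ampa_amp_pa=ampa, nmda_amp_pa=nmda,
                             call=call,
                             ratio=(nmda / ampa if nmda is not None
                                    and call == "responsive" else np.nan),
                             true_silent=truth.get(spine_id, {}).get("silent")))
    return pd.DataFrame(rows)


def stage_uncage_multi(cohort: Cohort) -> pd.DataFrame:
    rows = []
    for cell in cohort:
        singles_sw = cell.protocol("uncage_multi_single")
        ens_sw = cell.protocol("uncage_multi")
        if not ens_sw:
            continue
        singles = []
        for sw in singles_sw:
            t0 = uncaging._first_marker(sw)
            singles.append(uncaging.measure_uepsp(sw, t0))
        ens = {}
        for sw in ens_sw:
            ens.setdefault(int(sw.meta.get("count", 0)), []).append(sw)
        res = uncaging.summation_analysis(ens, singles)
        truth = cell.ground_truth.get("multi", {})
        silent = truth.get("silent", [])
        res_ns = None
        if any(silent):
            ens_ns = {c: sws for c, sws in ens.items()}
            singles_ns = [s for s, sil in zip(singles, silent) if not sil]
            # spines-to-AP excluding silent spines: count only the
            # non-silent members of each uncaged ensemble
            nonsilent_cum = np.cumsum([0 if s else 1 for s in silent])
            fired = [c for c, f in zip(res.counts, res.ap_fired) if f]
            res_ns = int(nonsilent_cum[min(fired) - 1]) if fired else None
        rows.append(dict(cell_id=cell.cell_id, genotype=cell.genotype,
                         animal_id=cell.animal_id, litter_id=cell.litter_id,
                         slice_id=cell.slice_id,
                         mean_single_mv=float(np.mean(singles)) if singles else np.nan,
                         linearity_slope=res.linearity_slope,
                         normalized_slope=res.normalized_slope,
                         spines_to_ap=res.spines_to_ap,
                         ap_censored=res.ap_censored,
                         spines_to_ap_excl_silent=res_ns))
    return pd.DataFrame(rows)


def stage_tca(cohort: Cohort) -> pd.DataFrame:
    rows = []
    for cell in cohort:
        for key in list(cell.sweeps):
            if not key.startswith("tca_train_"):
                continue
            freq = float(key.split("_")[-1])
            res = uncaging.train_spike_probability(cell.protocol(key), freq)
            rows.append(dict(cell_id=cell.cell_id, genotype=cell.genotype,
                             animal_id=cell.animal_id,
                             litter_id=cell.litter_id,
                             slice_id=cell.slice_id,
                             frequency_hz=freq, p_spike=res.p_spike,
                             n_trials=res.n_trials))
    return pd.DataFrame(rows)


def stage_mepsc(cohort: Cohort) -> pd.DataFrame:
    rows = []
    for cell in cohort:
        for key, label in (("mepsc_-70", "ampa"), ("mepsc_+40", "nmda")):
            sweeps = cell.protocol(key)
            if not sweeps:
                continue
            sw = sweeps[0]
            events = mepsc.detect_events(sw)
            st = mepsc.event_stats(events, sw.duration)
            rows.append(dict(cell_id=cell.cell_id, genotype=cell.genotype,
                             animal_id=cell.animal_id,
                             litter_id=cell.litter_id,
                             slice_id=cell.slice_id, receptor=label,
                             frequency_hz=st["frequency_hz"],
                             amp_mean_pa=st["amp_mean_pa"],
                             n_events=st["n"],
                             n_true=len(sw.marker_times("event"))))
    return pd.DataFrame(rows)


def compare_genotypes(table: pd.DataFrame, value_col: str,
                      family: str | None = None) -> stats.ComparisonResult:
    """Hierarchical WT-vs-KO comparison of one feature column."""
    df = table.dropna(subset=[value_col])
    vals = df[value_col].to_numpy(dtype=float)
    if family is None:
        try:
            family = stats.select_family(vals)
        except ValueError:
            family = "normal"
    if family != "normal" and np.any(vals <= 0):
        family = "normal"
    return stats.hierarchical_compare(
        vals, df["genotype"], df["animal_id"],
        litter=df["litter_id"] if "litter_id" in df else None,
        slice_=df["slice_id"] if "slice_id" in df else None,
        family=family)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, cohort: Cohort | None = None) -> dict:
    """Run the full analysis; returns the report dict and writes the bundle."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=1))
    if cohort is None:
        log.info("generating cohort (seed=%d)", config.seed)
        cohort = cohort_mod.generate_cohort(
            WT, KO, n_animals=config.n_animals,
            cells_per_animal=config.cells_per_animal,
            protocols=config.protocols, seed=config.seed,
            mepsc_duration_s=config.mepsc_duration_s)
        write_cohort(cohort, out / "cohort.h5")
    if len(cohort) == 0:
        raise ValueError("empty cohort")

    qc_rows = [dict(cell_id=c.cell_id,
                    decision=str(reject_cell(c, config.qc).accept),
                    reasons=";".join(reject_cell(c, config.qc).reasons))
               for c in cohort]
    pd.DataFrame(qc_rows).to_csv(out / "qc.csv", index=False)

    tables = {}
    stage_fns = dict(intrinsic=stage_intrinsic, ih=stage_ih,
                     uncage_seq=stage_uncage_seq,
                     uncage_multi=stage_uncage_multi,
                     tca=stage_tca, mepsc=stage_mepsc)
    for name, fn in stage_fns.items():
        try:
            t = fn(cohort)
        except Exception as exc:
            log.error("stage %s failed: %s", name, exc)
            raise
        tables[name] = t
        t.to_csv(out / f"{name}.csv", index=False)

    rng = np.random.default_rng(config.seed + 1)
    morph = pd.concat([
        cohort_mod.generate_morphology(WT, config.morphology_animals,
                                       seed=int(rng.integers(2**31))),
        cohort_mod.generate_morphology(KO, config.morphology_animals,
                                       seed=int(rng.integers(2**31)))])
    ultra = pd.concat([
        cohort_mod.generate_ultrastructure(
            WT, config.ultrastructure_animals[0],
            seed=int(rng.integers(2**31))),
        cohort_mod.generate_ultrastructure(
            KO, config.ultrastructure_animals[1],
            seed=int(rng.integers(2**31)))])
    morph.to_csv(out / "morphology.csv", index=False)
    ultra.to_csv(out / "ultrastructure.csv", index=False)
    tables["morphology"] = morph
    tables["ultrastructure"] = ultra

    report = _summary_report(tables)
    (out / "report.json").write_text(json.dumps(report, indent=1))
    return report


def _group_means(df, col, by="genotype"):
    if df.empty or col not in df:
        return {}
    return {str(g): float(v) for g, v in
            df.dropna(subset=[col]).groupby(by)[col].mean().items()}


def _summary_report(tables: dict) -> dict:
    rep: dict = {}
    t = tables.get("intrinsic", pd.DataFrame())
    rep["r_input_mohm"] = _group_means(t, "r_input_mohm")
    rep["rheobase_pa"] = _group_means(t, "rheobase_pa")
    rep["sag_pct"] = _group_means(t, "sag_pct")
    rep["rebound_slope"] = _group_means(t, "rebound_slope")
    rep["f_res_hz"] = _group_means(t, "f_res_hz")
    t = tables.get("ih", pd.DataFrame())
    rep["ih_v12_mv"] = _group_means(t, "v12_mv")
    t = tables.get("uncage_seq", pd.DataFrame())
    if not t.empty:
        resp = t[t.call == "responsive"]
        rep["uepsc_pa"] = _group_means(resp, "ampa_amp_pa")
        rep["silent_fraction"] = {
            str(g): float((grp.call == "silent").sum()
                          / max((grp.call != "unresponsive").sum(), 1))
            for g, grp in t.groupby("genotype")}
        rep["nmda_ampa_ratio"] = _group_means(resp, "ratio")
    t = tables.get("uncage_multi", pd.DataFrame())
    rep["linearity_slope"] = _group_means(t, "linearity_slope")
    rep["spines_to_ap"] = _group_means(t, "spines_to_ap")
    t = tables.get("tca", pd.DataFrame())
    if not t.empty:
        rep["p_spike"] = {
            f"{g}@{f:g}Hz": float(grp["p_spike"].mean())
            for (g, f), grp in t.groupby(["genotype", "frequency_hz"])}
    t = tables.get("mepsc", pd.DataFrame())
    if not t.empty:
        rep["mepsc_freq_hz"] = {
            f"{g}:{r}": float(grp["frequency_hz"].mean())
            for (g, r), grp in t.groupby(["genotype", "receptor"])}
    t = tables.get("ultrastructure", pd.DataFrame())
    if not t.empty:
        from .structure import mis_incidence
        _, group = mis_incidence(t)
        rep["mis_incidence_pct"] = group
    t = tables.get("morphology", pd.DataFrame())
    if not t.empty:
        from .structure import morph_summary
        ms = morph_summary(t)
        rep["head_width_um"] = _group_means(ms, "head_width_um")
    return rep
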