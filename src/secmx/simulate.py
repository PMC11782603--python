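"""Synthetic multiplexed SEC-MS experiments with known ground truth.

The generator emulates the structure of a two-condition, two-replicate SEC
co-fractionation experiment quantified with TMT reporter ions:

* each protein elutes in 1-3 Gaussian *assembly states*; the latest state
  sits at the fraction the molecular-weight calibration predicts for the
  monomer, earlier states are complexes;
* every peptide of a protein shares the protein's state profile scaled by a
  peptide-specific ionization amplitude;
* a configurable subset of states carries a planted between-condition fold
  change; a subset of proteins carries phosphopeptides, each assigned to one
  state with its own planted phospho fold change;
* fractions are pooled into TMT mixes — the global dataset in a
  ``full_overlap`` (each interior fraction measured in two adjacent mixes)
  or ``no_overlap`` scheme, the phospho dataset always in the no-overlap
  scheme whose mixes pool the same fractions of both conditions (the layout
  that makes phospho fold changes immune to mix-level batch effects);
* per-mix batch scale factors, multiplicative log-normal noise, a detection
  floor and random missingness perturb the reporter values.

The emitted tables are exactly what the readers in :mod:`secmx.io` consume;
:class:`SyntheticTruth` is sufficient to score apex recovery, fold-change
error, monomer/complex classification and phospho mapping without
re-simulation.

A note on fold-change ground truth: the pipeline scales the comparison
condition onto the reference by the ratio of nonzero intensity medians.
Under asymmetric planted regulation that median ratio is not exactly 1, so
every recovered ratio is shifted by a small data-dependent constant — an
inherent property of median normalization, not a pipeline defect.  The
truth table therefore records both the drawn fold change and the expected
fold change on the normalized scale (drawn minus the exactly computed
median shift of the noise-free, floor-censored signal); recovery metrics
score against the latter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .calibration import CalibrationStandard
from .model import DesignEntry, ExperimentDesign, ValidationError

__all__ = ["GeneratorConfig", "SyntheticTruth", "SimulatedExperiment", "simulate_experiment",
           "score_recovery", "RecoveryReport"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the simulated experiment (all rates in [0, 1])."""

    seed: int
    n_fractions: int = 54
    n_proteins: int = 200
    peptides_per_protein: tuple[int, int] = (3, 6)
    state_count_probs: tuple[float, ...] = (0.35, 0.45, 0.20)  # P(1), P(2), P(3) states
    monomer_apex_range: tuple[int, int] | None = None  # default: late fractions
    state_gap_range: tuple[int, int] = (12, 15)        # fractions between adjacent states
    min_apex: int = 4
    width_range: tuple[float, float] = (1.0, 1.6)      # Gaussian SD, fractions
    amplitude_range: tuple[float, float] = (5e3, 1e5)  # log-uniform peptide amplitudes
    occupancy_range: tuple[float, float] = (0.4, 1.0)  # per-state relative occupancy
    changed_state_prob: float = 0.3
    log2fc_magnitude_range: tuple[float, float] = (0.7, 1.585)
    phospho_protein_fraction: float = 0.3
    phospho_peptides_per_protein: tuple[int, int] = (1, 3)
    phospho_changed_prob: float = 0.4
    scheme: str = "full_overlap"                       # global dataset mixing scheme
    mix_width: int = 18                                # channels per mix
    batch_factors: tuple[float, ...] | None = None     # per global mix in chain order
    noise_sigma: float = 0.1                           # log-normal sigma
    detection_floor: float = 100.0
    missing_rate: float = 0.02
    conditions: tuple[str, str] = ("HEK293", "HCT116")
    n_replicates: int = 2
    cal_slope: float = -0.06                           # d log10(MW) / d fraction
    cal_intercept: float = 7.0                         # log10(MW Da) at fraction 0
    standard_fractions: tuple[int, ...] = (3, 10, 17, 24, 31, 38, 45, 52)
    standard_log10_noise_sd: float = 0.0
    monomer_mw_jitter: tuple[float, float] = (0.85, 1.15)
    decoy_peptides: int = 8
    nonproteotypic_peptides: int = 8

    def validate(self) -> None:
        stride = self.mix_width // 2
        if self.scheme == "full_overlap":
            if self.mix_width % 2 or self.n_fractions < self.mix_width or (
                (self.n_fractions - self.mix_width) % stride
            ):
                raise ValidationError(
                    "full_overlap needs an even mix width and n_fractions = width + k*width/2"
                )
        elif self.scheme == "no_overlap":
            if self.n_fractions % stride:
                raise ValidationError("no_overlap needs n_fractions divisible by mix_width/2")
        else:
            raise ValidationError(f"unknown scheme {self.scheme!r}")
        for r in (self.changed_state_prob, self.phospho_protein_fraction,
                  self.phospho_changed_prob, self.missing_rate):
            if not (0.0 <= r <= 1.0):
                raise ValidationError("rates must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth sufficient to score every recovery metric."""

    states: pd.DataFrame       # protein, state_idx, apex, width, occupancy,
                               # log2fc_drawn, log2fc_expected, is_monomer, monomer_mw
    phospho: pd.DataFrame      # peptide, protein, state_idx, apex, log2fc_drawn, log2fc_expected
    batch_factors: dict[tuple[str, str], list[float]]  # (condition, replicate) -> chain
    condition_bias_log2: dict[str, float]              # dataset -> log2 median shift
    seed: int = 0


@dataclass
class SimulatedExperiment:
    records: pd.DataFrame          # canonical quant schema + resolved condition/replicate/fraction
    design: ExperimentDesign
    standard: CalibrationStandard
    monomer_masses: dict[str, float]
    truth: SyntheticTruth


def _random_seq(rng: np.random.Generator, length: int) -> str:
    aas = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(rng.choice(list(aas), size=length))


def _gauss(frac: np.ndarray, apex: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((frac - apex) / width) ** 2)


def _mix_layout(cfg: GeneratorConfig) -> list[tuple[int, int]]:
    """Global-scheme mix windows as (first_fraction, last_fraction), chain order."""
    stride = cfg.mix_width // 2
    if cfg.scheme == "full_overlap":
        starts = range(1, cfg.n_fractions - cfg.mix_width + 2, stride)
        return [(s, s + cfg.mix_width - 1) for s in starts]
    # no_overlap: blocks of width/2 fractions, pooled across both conditions
    return [(s, s + stride - 1) for s in range(1, cfg.n_fractions + 1, stride)]


def simulate_experiment(config: GeneratorConfig) -> SimulatedExperiment:
    """Generate one experiment; identical seeds give bit-identical output."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    frac = np.arange(1, cfg.n_fractions + 1, dtype=float)
    cond_a, cond_b = cfg.conditions
    reps = [f"r{i + 1}" for i in range(cfg.n_replicates)]

    apex_hi = cfg.monomer_apex_range or (max(cfg.min_apex + 2, cfg.n_fractions - 18),
                                         cfg.n_fractions - 6)

    # ---- proteins, states, peptides -------------------------------------
    state_rows = []
    proteins = [f"P{i + 1:05d}" for i in range(cfg.n_proteins)]
    monomer_masses: dict[str, float] = {}
    prot_states: dict[str, list[dict]] = {}
    for prot in proteins:
        n_states = int(rng.choice(np.arange(1, len(cfg.state_count_probs) + 1),
                                  p=cfg.state_count_probs))
        monomer_apex = int(rng.integers(apex_hi[0], apex_hi[1] + 1))
        apexes = [monomer_apex]
        for _ in range(n_states - 1):
            gap = int(rng.integers(cfg.state_gap_range[0], cfg.state_gap_range[1] + 1))
            nxt = apexes[-1] - gap
            if nxt < cfg.min_apex:
                break
            apexes.append(nxt)
        states = []
        for k, apex in enumerate(apexes):
            width = float(rng.uniform(*cfg.width_range))
            occ = float(rng.uniform(*cfg.occupancy_range))
            if rng.random() < cfg.changed_state_prob:
                mag = rng.uniform(*cfg.log2fc_magnitude_range)
                fc = float(mag * rng.choice([-1.0, 1.0]))
            else:
                fc = 0.0
            states.append({"state_idx": k, "apex": apex, "width": width,
                           "occupancy": occ, "log2fc_drawn": fc,
                           "is_monomer": k == 0})
        prot_states[prot] = states
        mw_pred = 10.0 ** (cfg.cal_intercept + cfg.cal_slope * monomer_apex)
        monomer_masses[prot] = float(mw_pred * rng.uniform(*cfg.monomer_mw_jitter))
        for s in states:
            state_rows.append({"protein": prot, **s})

    # global peptides
    pep_rows = []
    for prot in proteins:
        n_pep = int(rng.integers(cfg.peptides_per_protein[0], cfg.peptides_per_protein[1] + 1))
        for _ in range(n_pep):
            amp = float(np.exp(rng.uniform(np.log(cfg.amplitude_range[0]),
                                           np.log(cfg.amplitude_range[1]))))
            seq = _random_seq(rng, int(rng.integers(8, 16)))
            group = prot
            if rng.random() < 0.1:  # shared accession exercises representative-ID rule
                group = f"{prot};Q{rng.integers(10000, 99999)}"
            pep_rows.append({"peptide": seq, "protein": prot, "group": group, "amp": amp})
    peps = pd.DataFrame(pep_rows)

    # phospho peptides: subset of proteins, each peptide pinned to one state
    n_ph_prot = int(round(cfg.phospho_protein_fraction * cfg.n_proteins))
    ph_proteins = list(rng.choice(proteins, size=n_ph_prot, replace=False))
    ph_rows = []
    for prot in ph_proteins:
        n_pp = int(rng.integers(cfg.phospho_peptides_per_protein[0],
                                cfg.phospho_peptides_per_protein[1] + 1))
        for _ in range(n_pp):
            seq = _random_seq(rng, int(rng.integers(8, 16)))
            pos = int(rng.integers(0, len(seq)))
            seq = seq[:pos] + str(rng.choice(list("STY"))) + seq[pos + 1:]
            state = prot_states[prot][int(rng.integers(0, len(prot_states[prot])))]
            amp = float(np.exp(rng.uniform(np.log(cfg.amplitude_range[0]),
                                           np.log(cfg.amplitude_range[1]))))
            if rng.random() < cfg.phospho_changed_prob:
                mag = rng.uniform(*cfg.log2fc_magnitude_range)
                fc = float(mag * rng.choice([-1.0, 1.0]))
            else:
                fc = 0.0
            prob = float(np.round(rng.beta(9, 1), 3))
            ph_rows.append({"peptide": seq, "protein": prot, "state_idx": state["state_idx"],
                            "apex": state["apex"], "width": state["width"], "amp": amp,
                            "log2fc_drawn": fc, "site_pos": pos + 1,
                            "site_res": seq[pos], "site_prob": prob})
    phospho = pd.DataFrame(ph_rows, columns=["peptide", "protein", "state_idx", "apex",
                                             "width", "amp", "log2fc_drawn", "site_pos",
                                             "site_res", "site_prob"])

    # ---- noise-free signal matrices (peptide x fraction, per condition) --
    def global_signal(cond: str) -> np.ndarray:
        sig = np.zeros((len(peps), cfg.n_fractions))
        for i, row in enumerate(peps.itertuples(index=False)):
            acc = np.zeros(cfg.n_fractions)
            for s in prot_states[row.protein]:
                r = 2.0 ** s["log2fc_drawn"] if cond == cond_b else 1.0
                acc += s["occupancy"] * r * _gauss(frac, s["apex"], s["width"])
            sig[i] = row.amp * acc
        return sig

    def phospho_signal(cond: str) -> np.ndarray:
        sig = np.zeros((len(phospho), cfg.n_fractions))
        for i, row in enumerate(phospho.itertuples(index=False)):
            r = 2.0 ** row.log2fc_drawn if cond == cond_b else 1.0
            sig[i] = row.amp * r * _gauss(frac, row.apex, row.width)
        return sig

    sig_g = {cond_a: global_signal(cond_a), cond_b: global_signal(cond_b)}
    sig_p = {cond_a: phospho_signal(cond_a), cond_b: phospho_signal(cond_b)}

    # ---- mixing layout, design, batch factors ----------------------------
    layout_g = _mix_layout(cfg)
    stride = cfg.mix_width // 2
    layout_p = [(s, s + stride - 1) for s in range(1, cfg.n_fractions + 1, stride)]
    chain = list(cfg.batch_factors) if cfg.batch_factors is not None else [1.0] * len(layout_g)
    if len(chain) != len(layout_g):
        raise ValidationError(
            f"batch_factors length {len(chain)} != number of global mixes {len(layout_g)}")

    entries: list[DesignEntry] = []
    truth_factors: dict[tuple[str, str], list[float]] = {}
    global_mixes: list[tuple[str, str, str, list[int], float]] = []  # (mix, cond, rep, fracs, bf)
    cross_global = cfg.scheme == "no_overlap"
    for rep in reps:
        if cross_global:
            for mi, (lo, hi) in enumerate(layout_g):
                mix = f"g_{rep}_m{mi + 1}"
                frs = list(range(lo, hi + 1))
                ch = 1
                for cond in (cond_a, cond_b):
                    for f in frs:
                        entries.append(DesignEntry(mix, f"c{ch:02d}", cond, rep, f))
                        ch += 1
                    global_mixes.append((mix, cond, rep, frs, chain[mi]))
            truth_factors[("*", rep)] = list(chain)
        else:
            for cond in (cond_a, cond_b):
                for mi, (lo, hi) in enumerate(layout_g):
                    mix = f"g_{cond}_{rep}_m{mi + 1}"
                    frs = list(range(lo, hi + 1))
                    for ch, f in enumerate(frs, start=1):
                        entries.append(DesignEntry(mix, f"c{ch:02d}", cond, rep, f))
                    global_mixes.append((mix, cond, rep, frs, chain[mi]))
                truth_factors[(cond, rep)] = list(chain)

    phospho_mixes: list[tuple[str, str, str, list[int], float]] = []
    if len(phospho):
        for rep in reps:
            for mi, (lo, hi) in enumerate(layout_p):
                mix = f"ph_{rep}_m{mi + 1}"
                frs = list(range(lo, hi + 1))
                ch = 1
                for cond in (cond_a, cond_b):
                    for f in frs:
                        entries.append(DesignEntry(mix, f"c{ch:02d}", cond, rep, f))
                        ch += 1
                    phospho_mixes.append((mix, cond, rep, frs, 1.0))
    design = ExperimentDesign(entries)

    # ---- emit records -----------------------------------------------------
    rec_frames: list[pd.DataFrame] = []

    def emit(mix: str, cond: str, rep: str, frs: list[int], bf: float,
             signal: np.ndarray, meta: pd.DataFrame, is_phospho: bool) -> None:
        cols = np.array(frs) - 1
        vals = signal[:, cols] * bf
        if cfg.noise_sigma > 0:
            vals = vals * rng.lognormal(0.0, cfg.noise_sigma, size=vals.shape)
        keep = vals >= cfg.detection_floor
        if cfg.missing_rate > 0:
            keep &= rng.random(vals.shape) >= cfg.missing_rate
        pi, fi = np.nonzero(keep)
        if pi.size == 0:
            return
        # channel of (cond, fraction) inside this mix
        grp = design.frame
        sel = grp[(grp["mix"] == mix) & (grp["condition"] == cond) & (grp["replicate"] == rep)]
        ch_of = dict(zip(sel["fraction"], sel["channel"]))
        frs_arr = np.array(frs)[fi]
        df = pd.DataFrame({
            "protein_ids": meta["protein" if is_phospho else "group"].to_numpy()[pi],
            "peptide_seq": meta["peptide"].to_numpy()[pi],
            "modified_seq": (meta["modified"].to_numpy()[pi] if is_phospho
                             else meta["peptide"].to_numpy()[pi]),
            "is_phospho": is_phospho,
            "site_probs": (meta["probstr"].to_numpy()[pi] if is_phospho else ""),
            "is_decoy": False,
            "is_proteotypic": True,
            "mix": mix,
            "channel": [ch_of[f] for f in frs_arr],
            "reporter_intensity": vals[pi, fi],
            "ms1_intensity": 0.0,  # filled below per (mix, modified_seq)
            "condition": cond,
            "replicate": rep,
            "fraction": frs_arr,
        })
        rec_frames.append(df)

    ph_meta = phospho.copy()
    if len(phospho):
        # modified sequence carries '[ph]' right after the phosphosite residue
        ph_meta["modified"] = [
            seq[:pos] + "[ph]" + seq[pos:] for seq, pos in zip(phospho["peptide"], phospho["site_pos"])
        ]
        ph_meta["probstr"] = [
            f"{r}:{p}:{q:g}" for r, p, q in zip(phospho["site_res"], phospho["site_pos"],
                                                phospho["site_prob"])
        ]

    for mix, cond, rep, frs, bf in global_mixes:
        emit(mix, cond, rep, frs, bf, sig_g[cond], peps, is_phospho=False)
    for mix, cond, rep, frs, bf in phospho_mixes:
        emit(mix, cond, rep, frs, bf, sig_p[cond], ph_meta, is_phospho=True)

    records = pd.concat(rec_frames, ignore_index=True)
    # MS1 = summed reporters of the spectrum (one precursor per mix & peptidoform)
    records["ms1_intensity"] = records.groupby(["mix", "modified_seq"])[
        "reporter_intensity"].transform("sum")

    records = pd.concat(
        [records, _nuisance_records(cfg, rng, design)], ignore_index=True)

    # ---- calibration standard and truth ----------------------------------
    log10mw = cfg.cal_intercept + cfg.cal_slope * np.asarray(cfg.standard_fractions, dtype=float)
    if cfg.standard_log10_noise_sd > 0:
        log10mw = log10mw + rng.normal(0.0, cfg.standard_log10_noise_sd, size=log10mw.shape)
    standard = CalibrationStandard(
        [(int(f), float(10.0 ** l)) for f, l in zip(cfg.standard_fractions, log10mw)]
    )

    bias = {
        "global": _median_shift(sig_g[cond_a], sig_g[cond_b], layout_g, chain, cfg),
        "phospho": (_median_shift(sig_p[cond_a], sig_p[cond_b], layout_p,
                                  [1.0] * len(layout_p), cfg) if len(phospho) else 0.0),
    }
    states_df = pd.DataFrame(state_rows)
    states_df["log2fc_expected"] = states_df["log2fc_drawn"] - bias["global"]
    states_df["monomer_mw"] = states_df["protein"].map(monomer_masses)
    if len(phospho):
        phospho = phospho.copy()
        phospho["log2fc_expected"] = phospho["log2fc_drawn"] - bias["phospho"]
    truth = SyntheticTruth(states=states_df, phospho=phospho,
                           batch_factors=truth_factors,
                           condition_bias_log2=dict(bias),
                           seed=cfg.seed)
    return SimulatedExperiment(records, design, standard, monomer_masses, truth)


def _median_shift(sig_a: np.ndarray, sig_b: np.ndarray,
                  layout: list[tuple[int, int]], chain: list[float],
                  cfg: GeneratorConfig) -> float:
    """log2 of the nonzero-median ratio the condition normalization will remove.

    Mirrors the pipeline's factor on the noise-free signal: a cell survives
    the detection floor when any covering mix's scaled value does; surviving
    values enter the median at their unscaled (chain-anchored) magnitude.
    """
    n_frac = sig_a.shape[1]
    best = np.zeros(n_frac)
    for (lo, hi), bf in zip(layout, chain):
        best[lo - 1:hi] = np.maximum(best[lo - 1:hi], bf)
    def masked(sig: np.ndarray) -> np.ndarray:
        mask = sig * best[None, :] >= cfg.detection_floor
        return sig[mask]
    va, vb = masked(sig_a), masked(sig_b)
    if va.size == 0 or vb.size == 0:
        return 0.0
    return float(np.log2(np.median(vb) / np.median(va)))


def _nuisance_records(cfg: GeneratorConfig, rng: np.random.Generator,
                      design: ExperimentDesign) -> pd.DataFrame:
    """Decoy and non-proteotypic filler records (removed by the filter stage)."""
    rows = []
    grp = design.frame
    for kind, n in (("decoy", cfg.decoy_peptides), ("nonproteo", cfg.nonproteotypic_peptides)):
        for i in range(n):
            seq = _random_seq(rng, 10)
            entry = grp.iloc[int(rng.integers(0, len(grp)))]
            rows.append({
                "protein_ids": f"XXX_{kind}{i + 1}",
                "peptide_seq": seq, "modified_seq": seq,
                "is_phospho": False, "site_probs": "",
                "is_decoy": kind == "decoy",
                "is_proteotypic": kind != "nonproteo",
                "mix": entry["mix"], "channel": entry["channel"],
                "reporter_intensity": float(rng.uniform(cfg.detection_floor, 1e4)),
                "ms1_intensity": float(rng.uniform(cfg.detection_floor, 1e4)),
                "condition": entry["condition"], "replicate": entry["replicate"],
                "fraction": int(entry["fraction"]),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# recovery scoring


@dataclass
class RecoveryReport:
    apex_recall: float
    apex_precision: float
    phospho_apex_recall: float
    fold_change_rmse: float
    fold_change_max_abs_error: float
    phospho_fold_change_rmse: float
    classification_accuracy: float
    phospho_mapping_accuracy: float
    n_true_states: int
    n_matched_states: int

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def score_recovery(truth: SyntheticTruth, result, apex_tol: int = 1) -> RecoveryReport:
    """Score a pipeline run against the generator's ground truth.

    ``result`` is the :class:`~secmx.pipeline.PipelineResult` of a run on the
    matching simulated experiment.  Apex recall/precision are evaluated per
    condition at +/- ``apex_tol`` fractions on the protein-level global peak
    sets; fold changes are compared against the expected (normalization-
    adjusted) planted values for states matched at the same tolerance.
    """
    conds = result.conditions
    # --- apex recall / precision on the global dataset
    true_apexes = {p: sorted(g["apex"]) for p, g in truth.states.groupby("protein")}
    hits = total = 0
    det_hits = det_total = 0
    for cond in conds:
        ps = result.peaksets.get(("global", cond), {})
        for prot, apexes in true_apexes.items():
            found = [p.apex for p in ps.get(prot, [])]
            for a in apexes:
                total += 1
                if any(abs(a - f) <= apex_tol for f in found):
                    hits += 1
        for prot, det in ps.items():
            for p in det:
                det_total += 1
                if any(abs(p.apex - a) <= apex_tol for a in true_apexes.get(prot, [])):
                    det_hits += 1
    recall = hits / total if total else float("nan")
    precision = det_hits / det_total if det_total else float("nan")

    # --- fold changes and classification on matched mutual states
    fc_err = []
    cls_ok = cls_n = 0
    truth_idx = {
        (r.protein, r.apex): r for r in truth.states.itertuples(index=False)
    }
    fc_by_state = {fc.state_id: fc.log2_ratio for fc in result.global_fold_changes}
    matched = 0
    for st in result.global_states:
        cand = [t for (p, a), t in truth_idx.items()
                if p == st.entity_id and abs(a - st.consensus_apex) <= apex_tol]
        if not cand:
            continue
        t = min(cand, key=lambda t: abs(t.apex - st.consensus_apex))
        matched += 1
        if st.state_id in fc_by_state and st.presence == "mutual":
            fc_err.append(fc_by_state[st.state_id] - t.log2fc_expected)
        if st.classification in ("monomeric", "complexed"):
            cls_n += 1
            want = "monomeric" if t.is_monomer else "complexed"
            cls_ok += st.classification == want
    fc_err = np.asarray(fc_err, dtype=float)
    rmse = float(np.sqrt(np.mean(fc_err**2))) if fc_err.size else float("nan")
    max_err = float(np.max(np.abs(fc_err))) if fc_err.size else float("nan")

    # --- phospho: peak recall, mapping accuracy, fold-change error
    ph_hits = ph_total = 0
    map_ok = map_n = 0
    for cond in conds:
        ps = result.peaksets.get(("phospho", cond), {})
        for r in truth.phospho.itertuples(index=False):
            ph_total += 1
            found = [p.apex for p in ps.get(r.peptide, [])]
            if any(abs(r.apex - f) <= apex_tol for f in found):
                ph_hits += 1
    true_ph_apex = dict(zip(truth.phospho["peptide"], truth.phospho["apex"]))
    for ann in result.ptm_annotations:
        if ann.status != "mapped":
            continue
        want = true_ph_apex.get(ann.peptide_id)
        if want is None:
            continue
        map_n += 1
        map_ok += abs(ann.global_apex - want) <= apex_tol
    ph_fc_err = []
    exp_ph = dict(zip(truth.phospho["peptide"], truth.phospho.get("log2fc_expected",
                                                                 truth.phospho.get("log2fc_drawn"))))
    for fc in result.phospho_fold_changes:
        if fc.peptide_id in exp_ph:
            ph_fc_err.append(fc.log2_ratio - exp_ph[fc.peptide_id])
    ph_fc_err = np.asarray(ph_fc_err, dtype=float)

    return RecoveryReport(
        apex_recall=recall,
        apex_precision=precision,
        phospho_apex_recall=ph_hits / ph_total if ph_total else float("nan"),
        fold_change_rmse=rmse,
        fold_change_max_abs_error=max_err,
        phospho_fold_change_rmse=(float(np.sqrt(np.mean(ph_fc_err**2)))
                                  if ph_fc_err.size else float("nan")),
        classification_accuracy=cls_ok / cls_n if cls_n else float("nan"),
        phospho_mapping_accuracy=map_ok / map_n if map_n else float("nan"),
        n_true_states=len(truth.states),
        n_matched_states=matched,
    )
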