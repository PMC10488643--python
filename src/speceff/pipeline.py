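"""End-to-end orchestration: simulate -> fingerprint -> bioassay -> models -> markers.

The marker search intersects two lines of evidence on the common peaks:
variable importance in projection (VIP > 1) from the PLSR model — hardened,
at the pipeline level, by requiring the exceedance to survive every
leave-one-out refit, which removes marginal chance correlations at small
cohort sizes — and the top-k Garson contribution ratios averaged over an
ensemble of LM-trained BP-ANNs, with k defaulting to the number of peaks
passing the VIP screen so the network acts as a confirmation of the
regression evidence.  A metabolomics branch
runs the filter chain, OPLS-DA with a permutation test, and the volcano
differential analysis.  Every run writes its artifacts plus a manifest to
an output directory and is byte-reproducible under a fixed config and seed.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import bioassay, chemometrics, fingerprint, metabolomics, neural, synthetic

#: compound identities of the 16 common peaks (C-codes used in the source cohort)
COMMON_PEAK_COMPOUNDS = {
    "C1": "chlorogenic acid",
    "C2": "neochlorogenic acid",
    "C3": "cryptochlorogenic acid",
    "C4": "isochlorogenic acid A",
    "C5": "isochlorogenic acid B",
    "C6": "linarin",
    "C7": "luteolin 7-glucoside",
    "C8": "apigenin-7-glucoside",
    "C9": "luteolin",
    "C10": "diosmetin",
    "C11": "luteolin 7-glucuronide",
    "C12": "diosmetin-7-glucoside",
    "C14": "quercetin",
    "C15": "apigenin",
    "C17": "caffeic acid",
    "C19": "apigenin-7-glucuronide",
}


@dataclass
class MarkerReport:
    """Per-peak marker evidence and the consensus selection."""

    peak_ids: list[str]
    vip: list[float]
    contribution: list[float]
    selected: list[str]
    vip_threshold: float
    top_k: int
    vip_stability: list[float] | None = None
    compound_names: dict = field(default_factory=dict)
    model_summaries: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def select_markers(
    vip,
    contributions,
    vip_threshold: float = 1.0,
    top_k: int | None = None,
    peak_ids: list[str] | None = None,
    compound_map: dict | None = None,
    vip_stability=None,
) -> MarkerReport:
    """Consensus marker rule: VIP > threshold AND top-k ANN contribution.

    ``top_k`` defaults to the number of peaks passing the VIP screen.  Ties
    in contribution rank are broken by peak id, so the selection is
    deterministic.

    ``vip_stability`` optionally supplies, per peak, the fraction of
    leave-one-out refits in which the peak's VIP exceeded the threshold; when
    given, the VIP screen additionally requires that fraction to be 1 (the
    importance must survive every single-sample perturbation).  Marginal
    chance correlations at small n fail this; genuinely response-linked peaks
    do not.
    """
    vip = np.asarray(vip, dtype=float)
    contributions = np.asarray(contributions, dtype=float)
    if vip.shape != contributions.shape:
        raise ValueError(
            f"VIP ({vip.shape}) and contribution ({contributions.shape}) "
            "vectors are not aligned"
        )
    if peak_ids is None:
        peak_ids = [f"P{j + 1:02d}" for j in range(vip.size)]
    if len(peak_ids) != vip.size:
        raise ValueError("peak_ids length does not match the vectors")
    if vip_stability is not None:
        vip_stability = np.asarray(vip_stability, dtype=float)
        if vip_stability.shape != vip.shape:
            raise ValueError("vip_stability is not aligned with the VIP vector")
        screen = (vip > vip_threshold) & (vip_stability >= 1.0)
    else:
        screen = vip > vip_threshold
    vip_pass = [pid for pid, ok in zip(peak_ids, screen) if ok]
    if top_k is None:
        top_k = len(vip_pass)
    order = sorted(range(len(peak_ids)),
                   key=lambda j: (-contributions[j], peak_ids[j]))
    top_contrib = {peak_ids[j] for j in order[:top_k]}
    selected = [pid for pid in peak_ids if pid in set(vip_pass) and pid in top_contrib]
    names = {}
    if compound_map:
        names = {pid: compound_map[pid] for pid in selected if pid in compound_map}
    return MarkerReport(
        peak_ids=list(peak_ids),
        vip=vip.tolist(),
        contribution=contributions.tolist(),
        selected=selected,
        vip_threshold=vip_threshold,
        top_k=top_k,
        vip_stability=None if vip_stability is None else vip_stability.tolist(),
        compound_names=names,
    )


DEFAULT_CONFIG = {
    "simulate": {
        "n_per_class": {"YJH": 8, "JH": 8},
        "common_count": 16,
        "class_extra_peaks": {"YJH": 10, "JH": 2},
        "n_causal": 3,
        "noise_sd": 0.1,
        "rt_jitter_sd": 0.05,
        "with_chromatograms": True,
    },
    "fingerprint": {
        "min_height": 5.0,
        "min_prominence": 5.0,
        "rt_tolerance": 0.25,
        "similarity_mode": "cosine",
    },
    "model": {
        "max_components": 3,  # the component budget of a 16-sample cohort
        "q2_folds": 7,
        "vip_threshold": 1.0,
        "vip_loo_stability": True,
        "n_hidden": 4,  # parsimonious for 16-sample cohorts; None = ceil((n_in+n_out)/2)
        "ann_ensemble": 9,
        "ann_max_iter": 150,
        "ann_patience": 20,
    },
    "metabolomics": {
        "enabled": True,
        "n_per_group": 10,
        "n_features": 120,
        "n_differential": 12,
        "fold_change": 2.0,
        "missing_rate": 0.1,
        "n_permutations": 200,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            out[k] = _merge(base[k], v)
        else:
            out[k] = v
    return out


def run_pipeline(config: dict | None = None, outdir=None, seed: int = 0) -> dict:
    """Run the full analysis and return a result dict.

    Stages: cohort simulation, fingerprint similarity + common peaks (from
    detected and matched chromatographic peaks when chromatograms are
    simulated, else from the truth table), bioactivity simulation and
    Y-matrix assembly, PLSR with Q2-based component selection and VIP,
    BP-ANN training with Garson contributions, consensus marker selection,
    and optionally the metabolomics branch.  When ``outdir`` is given, all
    artifacts and a manifest are written there.
    """
    t0 = time.time()
    config = _merge(DEFAULT_CONFIG, config or {})
    if "simulate" not in config or config["simulate"] is None:
        raise ValueError("pipeline config is missing the 'simulate' section")
    sim = config["simulate"]
    result: dict = {"config": config, "seed": seed, "stages": {}}

    # --- stage: simulate ---------------------------------------------------
    try:
        chroms, truth_table, truth = synthetic.simulate_cohort(
            n_per_class=sim["n_per_class"],
            common_count=sim["common_count"],
            class_extra_peaks=sim["class_extra_peaks"],
            seed=seed,
            n_causal=sim["n_causal"],
            noise_sd=sim["noise_sd"],
            rt_jitter_sd=sim["rt_jitter_sd"],
            with_chromatograms=sim["with_chromatograms"],
        )
    except Exception as err:
        raise RuntimeError(f"stage 'simulate' failed: {err}") from err

    # --- stage: fingerprint ------------------------------------------------
    fp = config["fingerprint"]
    try:
        if chroms:
            resampled = fingerprint.resample_chromatograms(chroms)
            sim_report = fingerprint.similarity_report(
                resampled, mode=fp["similarity_mode"]
            )
            per_sample = [
                fingerprint.detect_peaks(c, fp["min_height"], fp["min_prominence"])
                for c in chroms
            ]
            table = fingerprint.match_peaks(
                per_sample, fp["rt_tolerance"],
                sample_ids=[c.sample_id for c in chroms],
            )
        else:
            sim_report = None
            table = truth_table
        common = fingerprint.common_peaks(table)
    except Exception as err:
        raise RuntimeError(f"stage 'fingerprint' failed: {err}") from err
    result["stages"]["fingerprint"] = {
        "n_matched_peaks": len(table.peak_ids),
        "n_common_peaks": len(common),
        "similarity": None if sim_report is None
        else sim_report["similarity"].tolist(),
    }

    # --- stage: bioassay (activity matrix) ---------------------------------
    try:
        activity = synthetic.simulate_bioactivity(truth_table, truth)
        Y = bioassay.build_activity_matrix(activity, harmonise="none")
    except Exception as err:
        raise RuntimeError(f"stage 'bioassay' failed: {err}") from err

    # --- stage: model (PLSR + VIP, ANN + contributions) ---------------------
    mod = config["model"]
    try:
        # model on the common peaks of the ground-truth table: column indices
        # are stable there, and the matched table is reported separately
        common_truth = fingerprint.common_peaks(truth_table)
        X = truth_table.areas[common_truth]
        max_comp = min(mod["max_components"], X.shape[1], X.shape[0] - 1)
        q2 = chemometrics.q2_cross_validation(
            X.to_numpy(), Y.to_numpy(), max_comp,
            n_folds=min(mod["q2_folds"], X.shape[0]), seed=seed,
        )
        n_comp = chemometrics.select_n_components(q2)
        plsr = chemometrics.plsr_fit(X, Y, n_comp)
        vip_vals = chemometrics.vip(plsr)

        stability = None
        if mod["vip_loo_stability"]:
            Xv, Yv = X.to_numpy(), Y.to_numpy()
            n = Xv.shape[0]
            counts = np.zeros(Xv.shape[1])
            for i in range(n):
                keep = np.delete(np.arange(n), i)
                v_i = chemometrics.vip(chemometrics.plsr_fit(Xv[keep], Yv[keep], n_comp))
                counts += v_i > mod["vip_threshold"]
            stability = counts / n

        n_in = X.shape[1]
        n_hidden = mod["n_hidden"] or neural.default_hidden_size(n_in, Y.shape[1])
        ratio_stack = []
        mse_triples = []
        for k in range(mod["ann_ensemble"]):
            member_seed = seed * 1000 + k
            net = neural.init_network(n_in, n_hidden, Y.shape[1], seed=member_seed)
            fit = neural.train(
                net, X.to_numpy(), Y.to_numpy(),
                max_iter=mod["ann_max_iter"], patience=mod["ann_patience"],
                seed=member_seed,
            )
            ratio_stack.append(neural.contribution_ratios(fit.network).ratios)
            mse_triples.append(fit.mse)
        contrib_ratios = np.mean(ratio_stack, axis=0)
        mse_mean = np.mean(mse_triples, axis=0)
    except Exception as err:
        raise RuntimeError(f"stage 'model' failed: {err}") from err

    report = select_markers(
        vip_vals, contrib_ratios, vip_threshold=mod["vip_threshold"],
        peak_ids=list(X.columns), vip_stability=stability,
    )
    report.model_summaries = {
        "plsr": {
            "n_components": n_comp,
            "r2x_per_component": plsr.r2x.tolist(),
            "r2y_per_component": plsr.r2y.tolist(),
            "r2x_cum": float(plsr.r2x_cum[-1]),
            "r2y_cum": float(plsr.r2y_cum[-1]),
            "q2_per_component": np.asarray(q2).tolist(),
            "q2": float(q2[n_comp - 1]),
        },
        "ann": {
            "architecture": [n_in, n_hidden, Y.shape[1]],
            "ensemble_size": mod["ann_ensemble"],
            "mse_train": float(mse_mean[0]),
            "mse_val": float(mse_mean[1]),
            "mse_test": float(mse_mean[2]),
        },
    }
    report.seeds = {"pipeline": seed}
    causal_ids = [truth_table.peak_ids[i] for i in truth.causal_peak_indices]
    result["stages"]["model"] = report.model_summaries
    result["marker_report"] = report
    result["truth"] = {
        "causal_peak_ids": causal_ids,
        "common_peak_ids": [truth_table.peak_ids[i]
                            for i in truth.common_peak_indices],
    }

    # --- stage: metabolomics ------------------------------------------------
    met = config["metabolomics"]
    if met.get("enabled", True):
        try:
            raw, met_truth = synthetic.simulate_metabolome(
                n_per_group=met["n_per_group"],
                n_features=met["n_features"],
                n_differential=met["n_differential"],
                fold_change=met["fold_change"],
                missing_rate=met["missing_rate"],
                seed=seed + 1,
            )
            filtered, logs = metabolomics.preprocess(raw)
            perm = chemometrics.permutation_test(
                filtered.intensities, filtered.groups,
                n_permutations=met["n_permutations"], seed=seed,
                scale="pareto",
            )
            diff = chemometrics.volcano(filtered, seed=seed)
        except Exception as err:
            raise RuntimeError(f"stage 'metabolomics' failed: {err}") from err
        result["stages"]["metabolomics"] = {
            "filter_logs": [lg.to_dict() for lg in logs],
            "n_features_retained": len(filtered.feature_ids),
            "permutation": {
                "r2y_observed": perm["r2y_observed"],
                "q2_observed": perm["q2_observed"],
                "p_r2y": perm["p_r2y"],
                "p_q2": perm["p_q2"],
            },
            "n_selected_differential": int(diff["selected"].sum()),
            "planted_differential": met_truth["differential_features"],
        }
        result["volcano"] = diff

    result["elapsed_s"] = time.time() - t0

    if outdir is not None:
        _write_artifacts(result, table, truth_table, Y, outdir)
    return result


def _write_artifacts(result: dict, table, truth_table, Y, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}
    table.to_csv(outdir / "peak_table.csv")
    files["peak_table.csv"] = "matched samples x peaks area table"
    truth_table.to_csv(outdir / "truth_peak_table.csv")
    files["truth_peak_table.csv"] = "generator ground-truth peak areas"
    Y.to_csv(outdir / "activity_matrix.csv", index_label="sample_id")
    files["activity_matrix.csv"] = "samples x endpoints Y-matrix"
    result["marker_report"].to_json(outdir / "marker_report.json")
    files["marker_report.json"] = "VIP/contribution evidence and selected markers"
    if "volcano" in result:
        result["volcano"].to_csv(outdir / "volcano.csv", index_label="feature_id")
        files["volcano.csv"] = "per-feature differential statistics"
    manifest = {
        "seed": result["seed"],
        "config": result["config"],
        "elapsed_s": result["elapsed_s"],
        "stages": {
            k: v for k, v in result["stages"].items() if k != "fingerprint"
        } | {"fingerprint": {
            kk: vv for kk, vv in result["stages"]["fingerprint"].items()
        }},
        "files": files,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
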