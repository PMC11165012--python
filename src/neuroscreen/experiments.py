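"""End-to-end recovery experiments on the packaged fixture conditions.

Each function regenerates synthetic data from a fixture config at a given
seed, runs the corresponding analysis pipeline from scratch and returns
the recovered quantities together with the generator's ground truth.
These drive both the acceptance script and the acceptance test suite.
"""

from __future__ import annotations

import numpy as np

from . import imaging, mea, screen
from .io import load_fixture
from .simulate import (
    simulate_dose_response,
    simulate_field,
    simulate_screen,
    simulate_spike_trains,
)


def _sub_seed(seed: int, offset: int) -> int:
    return (int(seed) * 1000 + offset) % (2**31 - 1)


# ------------------------------------------------------------------ screen


def run_screen_experiment(seed: int) -> dict:
    """Full-scale duplicate screen: hit count, concordance and mean Z'."""
    cfg = load_fixture("screen_sim.yaml")
    table, truth = simulate_screen(cfg, seed)
    res = screen.ScreenModel(table).fit()
    return {
        "n_hits": res.n_hits,
        "hits": res.hits,
        "pearson_ki67": res.concordance["pearson_ki67"],
        "pearson_hucd": res.concordance["pearson_hucd"],
        "mean_zprime_ki67": res.mean_z_prime("ki67"),
        "mean_zprime_hucd": res.mean_z_prime("hucd"),
        "n_compound_wells": int((table["role"] == "compound").sum()),
        "truth": truth,
        "results": res,
    }


# ----------------------------------------------------------- differentiation


def run_differentiation_experiment(seed: int, condition: str = "DMSO",
                                   n_fields: int = 50) -> dict:
    """Segment synthetic D6 fields and recover the marker positivity ratios.

    Per field: illumination correction, nuclei segmentation, marker
    positivity, live-only ratios; the well-style mean over fields is
    reported next to the generator's realized ground-truth fractions.
    """
    cfg = load_fixture("imaging_d6.yaml")
    results = []
    true_ki, true_hu, true_live = 0, 0, 0
    for i in range(n_fields):
        img, truth = simulate_field(cfg, condition, _sub_seed(seed, i))
        img = imaging.correct_illumination(img)
        nuclei, labels = imaging.segment_nuclei(img)
        nuclei = imaging.score_marker_positivity(nuclei, labels, img)
        ki, hu, n_live, n_dead, n_debris = imaging.compute_ratios(nuclei)
        results.append({"ki67_ratio": ki, "hucd_ratio": hu, "n_live": n_live,
                        "n_dead": n_dead, "n_debris": n_debris})
        live = [n for n in truth.nuclei if n["cls"] == "live"]
        true_live += len(live)
        true_ki += sum(n["ki67"] for n in live)
        true_hu += sum(n["hucd"] for n in live)
    well = imaging.aggregate_well(results)
    return {
        "ki67_pct": 100.0 * well.ki67_ratio,
        "hucd_pct": 100.0 * well.hucd_ratio,
        "true_ki67_pct": 100.0 * true_ki / true_live,
        "true_hucd_pct": 100.0 * true_hu / true_live,
        "mean_live_per_field": well.n_live,
        "n_fields": n_fields,
    }


# ---------------------------------------------------------------- synapses


def _synapse_counts(cfg, condition, seed, n_fields):
    counts, true_counts, shank3_int = [], [], []
    for i in range(n_fields):
        img, truth = simulate_field(cfg, condition, _sub_seed(seed, i))
        img = imaging.correct_illumination(img)
        skel = imaging.skeletonize_neurites(img)
        syn = imaging.detect_puncta(img, "Synapsin1")
        sh = imaging.detect_puncta(img, "SHANK3")
        synapses = imaging.call_synapses(syn, sh, skel)
        counts.append(len(synapses))
        true_counts.append(0 if truth.synapses is None else len(truth.synapses))
        if synapses:
            shank3_int.append(float(np.mean(
                [s.shank3_integrated_intensity for s in synapses])))
    return {
        "mean_synapses": float(np.mean(counts)),
        "true_mean_synapses": float(np.mean(true_counts)),
        "mean_synaptic_shank3_intensity": float(np.mean(shank3_int)) if shank3_int else float("nan"),
    }


def run_synapse_experiment(seed: int, n_fields: int = 30) -> dict:
    """WT-like vs HT-like D30 fields: the mutant/control synapse-count ratio.

    The two conditions are rendered at the same field seeds, so they share
    neurite skeletons and the count ratio isolates the synapse-density
    difference (a paired, common-random-numbers comparison).
    """
    cfg = load_fixture("synapse_d30.yaml")
    wt = _synapse_counts(cfg, "WT2_DMSO", seed, n_fields)
    ht = _synapse_counts(cfg, "HT3_DMSO", seed, n_fields)
    return {
        "wt": wt,
        "ht": ht,
        "synapse_ratio": ht["mean_synapses"] / wt["mean_synapses"],
        "true_ratio": ht["true_mean_synapses"] / wt["true_mean_synapses"],
        "n_fields": n_fields,
    }


# ------------------------------------------------------------ colocalization


def run_coloc_experiment(seed: int, condition: str, n_fields: int = 30) -> dict:
    """ARPC2-over-ß-actin overlap fraction averaged over synthetic fields."""
    cfg = load_fixture("coloc.yaml")
    fracs, true_fracs = [], []
    for i in range(n_fields):
        img, truth = simulate_field(cfg, condition, _sub_seed(seed, i))
        img = imaging.correct_illumination(img)
        fracs.append(imaging.coloc_fraction(img, "ARPC2", "bActin"))
        true_fracs.append(truth.coloc_fraction)
    return {
        "coloc_pct": 100.0 * float(np.nanmean(fracs)),
        "true_coloc_pct": 100.0 * float(np.nanmean(true_fracs)),
        "n_fields": n_fields,
    }


# ------------------------------------------------------------------- MEA


def run_mea_experiment(seed: int, condition: str) -> dict:
    """One simulated MEA well: the three per-well activity features."""
    cfg = load_fixture("mea.yaml")
    trains, truth = simulate_spike_trains(cfg, condition, seed)
    feats = mea.well_features(trains)
    return {
        "activity_hz": feats.activity_hz,
        "synchrony": feats.synchrony,
        "oscillation": feats.oscillation,
        "n_active_electrodes": feats.n_active_electrodes,
        "truth": truth,
    }


# ------------------------------------------------------------ dose response


def run_dose_experiment(seed: int) -> dict:
    """42-compound dose set: count of mutant-specific proliferation hits."""
    cfg = load_fixture("dose.yaml")
    table, truth = simulate_dose_response(cfg, seed)
    sel = screen.select_specific_compounds(
        table, mutant_line=str(cfg["dose_sim"]["mutant_line"]),
        control_line=str(cfg["dose_sim"]["control_line"]))
    return {
        "n_prolif_specific": int(sel["specific_prolif"].sum()),
        "n_selected": int(sel["selected"].sum()),
        "selection": sel,
        "truth": truth,
    }
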