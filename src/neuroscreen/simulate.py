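"""Synthetic data generators with known ground truth.

Every generator is deterministic given (config, seed): each draws from a
stream keyed by the global seed and a stage name, so fields, screens,
dose sets and spike trains can be regenerated independently.

The generators emulate the statistical structure the downstream analysis
assumes — nuclei as noisy ellipses with marker painting, neurites as
random branching trees with Gaussian cross-section, synaptic puncta as 2-D
Gaussians placed on or off the neurite skeleton, screens as latent
per-compound effects plus plate jitter and well noise, and spike trains as
(optionally correlated or bursting) Poisson processes. They do not attempt
photorealism; see the methods note for what that implies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as draw_ellipse

from .core import ConfigError, FieldImage, SpikeTrainSet, WellRole, rng_for, well_name

# --------------------------------------------------------------- ground truth


@dataclass
class FieldTruth:
    """What was actually rendered into one synthetic field."""

    nuclei: list = field(default_factory=list)  # dicts: center, radii, cls, ki67, hucd
    skeleton_points: np.ndarray | None = None   # (N, 2) float points along neurites
    skeleton_length_um: float = 0.0
    puncta: dict = field(default_factory=dict)  # channel -> (N, 2) centers
    synapses: np.ndarray | None = None          # (N, 2) paired punctum centers
    coloc_fraction: float | None = None         # realized area fraction, ARPC2 in actin
    condition: str = ""

    def marker_fraction(self, marker: str) -> float:
        live = [n for n in self.nuclei if n["cls"] == "live"]
        if not live:
            return float("nan")
        return sum(1 for n in live if n[marker]) / len(live)


@dataclass
class ScreenTruth:
    active_ids: list
    toxic_ids: list
    latent_ki67: dict
    latent_hucd: dict


@dataclass
class MEATruth:
    rates_hz: dict
    rho: float


def _check_fraction(x, name):
    if not 0.0 <= float(x) <= 1.0:
        raise ConfigError(f"{name} must be in [0, 1], got {x}")
    return float(x)


def _condition_block(cfg: dict, condition: str) -> dict:
    conds = cfg.get("conditions", {})
    if condition not in conds:
        raise ConfigError(f"unknown condition {condition!r} (have {sorted(conds)})")
    return conds[condition]


# --------------------------------------------------------------- field images


def _stamp_gaussian(img: np.ndarray, r: float, c: float, sigma: float, amp: float) -> None:
    """Add a 2-D Gaussian spot in place (window of 4 sigma)."""
    h, w = img.shape
    rad = max(2, int(math.ceil(4 * sigma)))
    r0, r1 = max(0, int(r) - rad), min(h, int(r) + rad + 1)
    c0, c1 = max(0, int(c) - rad), min(w, int(c) + rad + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    img[r0:r1, c0:c1] += amp * np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2 * sigma**2))


def _place_nuclei(rng, shape, ncfg):
    """Rejection-sample nucleus centers/sizes with near-disjoint footprints."""
    h, w = shape
    n = rng.poisson(float(ncfg["per_field"]))
    rmin, rmax = ncfg["radius_px"]
    placed = []
    tries = 0
    while len(placed) < n and tries < 40 * n + 200:
        tries += 1
        rad = rng.uniform(rmin, rmax)
        r, c = rng.uniform(rad, h - rad), rng.uniform(rad, w - rad)
        ok = all(
            (r - p["center"][0]) ** 2 + (c - p["center"][1]) ** 2
            > (0.95 * (rad + p["radii"][0])) ** 2
            for p in placed
        )
        if ok:
            ecc = rng.uniform(0.8, 1.0)
            placed.append(
                {
                    "center": (r, c),
                    "radii": (rad, rad * ecc),
                    "angle": rng.uniform(0, math.pi),
                }
            )
    return placed


def _grow_trees(rng, shape, tcfg, pixel_size_um):
    """Random binary neurite trees; returns dense polyline points and length (µm)."""
    h, w = shape
    pts_all = []
    total_len_px = 0.0
    seg_mean_px = float(tcfg["segment_mean_um"]) / pixel_size_um
    for _ in range(int(tcfg["n_trees"])):
        root = np.array([rng.uniform(0.1 * h, 0.9 * h), rng.uniform(0.1 * w, 0.9 * w)])
        heading = rng.uniform(0, 2 * math.pi)
        stack = [(root, heading, 0)]
        while stack:
            pos, ang, level = stack.pop()
            length = min(max(rng.exponential(seg_mean_px), 5.0), 3 * seg_mean_px)
            end = pos + length * np.array([math.sin(ang), math.cos(ang)])
            # truncate at the field boundary and stop the branch there
            t = 1.0
            for dim, lim in ((0, h - 1), (1, w - 1)):
                if end[dim] < 0:
                    t = min(t, (0 - pos[dim]) / (end[dim] - pos[dim]))
                elif end[dim] > lim:
                    t = min(t, (lim - pos[dim]) / (end[dim] - pos[dim]))
            end = pos + t * (end - pos)
            seg_len = float(np.hypot(*(end - pos)))
            if seg_len < 1.0:
                continue
            npts = max(2, int(seg_len / 0.5))
            frac = np.linspace(0.0, 1.0, npts)[:, None]
            pts_all.append(pos[None, :] * (1 - frac) + end[None, :] * frac)
            total_len_px += seg_len
            if t == 1.0 and level < int(tcfg["levels"]):
                spread = math.radians(rng.normal(28.0, 8.0))
                stack.append((end, ang + spread, level + 1))
                stack.append((end, ang - spread, level + 1))
    pts = np.concatenate(pts_all) if pts_all else np.empty((0, 2))
    return pts, total_len_px * pixel_size_um


def simulate_field(cfg: dict, condition: str, seed: int):
    """Render one synthetic field and its ground truth.

    The channels present depend on which sections the config enables:
    ``nuclei`` (Hoechst + Ki67/HuC-D painting), ``neurites``/``puncta``
    (MAP2, Synapsin1, SHANK3) and ``coloc`` (ARPC2, bActin). A
    multiplicative illumination gradient and additive Gaussian noise are
    applied last.
    """
    icfg = cfg["image_sim"]
    cond = _condition_block(cfg, condition)
    rng = rng_for(seed, f"field:{condition}")
    h, w = (int(x) for x in icfg["field_shape"])
    pixel_size = float(icfg["pixel_size_um"])
    background = float(icfg.get("background", 100.0))
    truth = FieldTruth(condition=condition)

    layers: dict[str, np.ndarray] = {}

    def layer(name):
        if name not in layers:
            layers[name] = np.zeros((h, w), dtype=float)
        return layers[name]

    # ---- nuclei + marker painting
    if "nuclei" in icfg:
        ncfg = icfg["nuclei"]
        dead_f = _check_fraction(ncfg.get("dead_fraction", 0.0), "dead_fraction")
        debris_f = _check_fraction(ncfg.get("debris_fraction", 0.0), "debris_fraction")
        ki67_f = _check_fraction(cond.get("ki67_fraction", 0.0), "ki67_fraction")
        hucd_f = _check_fraction(cond.get("hucd_fraction", 0.0), "hucd_fraction")
        coverage = _check_fraction(cond.get("marker_coverage", 1.0), "marker_coverage")
        nuc = layer("Hoechst")
        base_int = float(ncfg["intensity_mean"])
        for spot in _place_nuclei(rng, (h, w), ncfg):
            u = rng.random()
            if u < debris_f:
                cls = "debris"
                rr = rng.uniform(*ncfg.get("debris_radius_px", [2, 4]))
                radii = (rr, rr)
                amp = base_int * float(ncfg.get("debris_intensity_mult", 0.6))
            elif u < debris_f + dead_f:
                cls = "dead"
                m = float(ncfg.get("dead_size_mult", 0.65))
                radii = (spot["radii"][0] * m, spot["radii"][1] * m)
                amp = base_int * float(ncfg.get("dead_intensity_mult", 2.2))
            else:
                cls = "live"
                radii = spot["radii"]
                amp = rng.normal(base_int, float(ncfg.get("intensity_sd", 0.1 * base_int)))
            amp = max(amp, 0.2 * base_int)
            r, c = spot["center"]
            rr_px, cc_px = draw_ellipse(r, c, radii[0], radii[1],
                                        rotation=spot["angle"], shape=(h, w))
            nuc[rr_px, cc_px] += amp
            rec = {"center": (r, c), "radii": radii, "cls": cls,
                   "ki67": False, "hucd": False, "area_px": rr_px.size}
            if cls == "live":
                rec["ki67"] = bool(rng.random() < ki67_f)
                rec["hucd"] = bool(rng.random() < hucd_f)
                mk_amp = float(cond.get("marker_snr", 10.0)) * float(icfg.get("noise_sd", 8.0))
                cov = math.sqrt(coverage)
                for mk, chan in (("ki67", "Ki67"), ("hucd", "HuCD")):
                    if rec[mk]:
                        mr, mc = draw_ellipse(r, c, radii[0] * cov, radii[1] * cov,
                                              rotation=spot["angle"], shape=(h, w))
                        layer(chan)[mr, mc] += mk_amp
            truth.nuclei.append(rec)
        layer("Ki67")
        layer("HuCD")
        # smooth the hard ellipse edges slightly
        for name in ("Hoechst", "Ki67", "HuCD"):
            layers[name] = gaussian_filter(layers[name], 0.8)

    # ---- neurites and synaptic puncta
    if "neurites" in icfg:
        tcfg = icfg["neurites"]
        # geometry is keyed by seed only, so conditions rendered at the same
        # seed share skeletons: between-condition comparisons (e.g. synapse
        # density ratios) then cancel the skeleton-length variability
        rng_geom = rng_for(seed, "field-geometry")
        pts, length_um = _grow_trees(rng_geom, (h, w), tcfg, pixel_size)
        truth.skeleton_points = pts
        truth.skeleton_length_um = length_um
        map2 = layer("MAP2")
        if len(pts):
            idx = np.clip(np.round(pts).astype(int), 0, [h - 1, w - 1])
            map2[idx[:, 0], idx[:, 1]] = float(tcfg["amplitude"])
        layers["MAP2"] = gaussian_filter(map2, float(tcfg.get("sigma_px", 1.5)))

        pcfg = icfg.get("puncta", {})
        psigma = float(pcfg.get("sigma_px", 1.8))
        pamp = float(pcfg.get("amplitude", 500.0))
        pamp_sd = float(pcfg.get("amplitude_sd", 0.15 * pamp))
        sh_scale = float(cond.get("shank3_amp_scale", 1.0))
        syn_ch, sh_ch = layer("Synapsin1"), layer("SHANK3")

        def on_skel_positions(density_per_100um):
            lam = density_per_100um * length_um / 100.0
            k = rng.poisson(lam) if lam > 0 else 0
            if k == 0 or len(pts) == 0:
                return np.empty((0, 2))
            sel = rng.integers(0, len(pts), size=k)
            return pts[sel] + rng.normal(0, 0.4, size=(k, 2))

        def off_skel_positions(n_mean):
            k = rng.poisson(float(n_mean)) if n_mean > 0 else 0
            out = []
            tries = 0
            while len(out) < k and tries < 50 * k + 50:
                tries += 1
                p = np.array([rng.uniform(5, h - 5), rng.uniform(5, w - 5)])
                if len(pts) == 0 or np.min(np.sum((pts - p) ** 2, axis=1)) > 8.0**2:
                    out.append(p)
            return np.array(out) if out else np.empty((0, 2))

        syn_centers = []
        sh_centers = []
        pairs = on_skel_positions(float(cond.get("synapses_per_100um", 0.0)))
        for p in pairs:
            _stamp_gaussian(syn_ch, p[0], p[1], psigma, max(rng.normal(pamp, pamp_sd), 0.3 * pamp))
            _stamp_gaussian(sh_ch, p[0], p[1], psigma,
                            max(rng.normal(pamp, pamp_sd), 0.3 * pamp) * sh_scale)
            syn_centers.append(p)
            sh_centers.append(p)
        for p in on_skel_positions(float(cond.get("extra_synapsin_per_100um", 0.0))):
            _stamp_gaussian(syn_ch, p[0], p[1], psigma, max(rng.normal(pamp, pamp_sd), 0.3 * pamp))
            syn_centers.append(p)
        for p in on_skel_positions(float(cond.get("extra_shank3_per_100um", 0.0))):
            _stamp_gaussian(sh_ch, p[0], p[1], psigma,
                            max(rng.normal(pamp, pamp_sd), 0.3 * pamp) * sh_scale)
            sh_centers.append(p)
        for chan, centers, scale in (("Synapsin1", syn_centers, 1.0), ("SHANK3", sh_centers, sh_scale)):
            for p in off_skel_positions(float(cond.get("off_skeleton_per_field", 0.0))):
                _stamp_gaussian(layers[chan], p[0], p[1], psigma,
                                max(rng.normal(pamp, pamp_sd), 0.3 * pamp) * scale)
                centers.append(p)
        truth.puncta["Synapsin1"] = np.array(syn_centers) if syn_centers else np.empty((0, 2))
        truth.puncta["SHANK3"] = np.array(sh_centers) if sh_centers else np.empty((0, 2))
        truth.synapses = pairs

    # ---- two-channel colocalization fields
    if "coloc" in icfg:
        ccfg = icfg["coloc"]
        frac = _check_fraction(cond.get("coloc_fraction", 0.0), "coloc_fraction")
        actin, arpc2 = layer("bActin"), layer("ARPC2")
        amin, amax = ccfg.get("actin_radius_px", [5, 8])
        actin_blobs = []
        for _ in range(int(ccfg.get("n_actin_blobs", 60))):
            rad = rng.uniform(amin, amax)
            r, c = rng.uniform(amax, h - amax), rng.uniform(amax, w - amax)
            rr, cc = draw_ellipse(r, c, rad, rad, shape=(h, w))
            actin[rr, cc] += float(ccfg.get("amplitude", 500.0))
            actin_blobs.append((r, c, rad))
        # co-placed blobs take distinct actin hosts and off-placed blobs keep
        # clear of actin and of each other, so the realized area fraction
        # tracks the target without accidental unions
        n_blobs = int(ccfg.get("n_arpc2_blobs", 80))
        n_co = min(int(round(frac * n_blobs)), len(actin_blobs))
        hosts = rng.choice(len(actin_blobs), size=n_co, replace=False)
        co_area = off_area = 0.0
        placed_off = []
        for k in range(n_blobs):
            if k < n_co:
                br, bc, brad = actin_blobs[hosts[k]]
                rad = 0.7 * brad
                rr, cc = draw_ellipse(br, bc, rad, rad, shape=(h, w))
                co_area += rr.size
            else:
                rad = rng.uniform(0.7 * amin, 0.7 * amax)
                for _ in range(200):
                    r, c = rng.uniform(amax, h - amax), rng.uniform(amax, w - amax)
                    if all((r - br) ** 2 + (c - bc) ** 2 > (brad + rad + 3) ** 2
                           for br, bc, brad in actin_blobs) and all(
                           (r - pr) ** 2 + (c - pc) ** 2 > (prad + rad + 2) ** 2
                           for pr, pc, prad in placed_off):
                        break
                rr, cc = draw_ellipse(r, c, rad, rad, shape=(h, w))
                placed_off.append((r, c, rad))
                off_area += rr.size
            arpc2[rr, cc] += float(ccfg.get("amplitude", 500.0)) * 0.9
        total = co_area + off_area
        truth.coloc_fraction = co_area / total if total else float("nan")
        layers["bActin"] = gaussian_filter(layers["bActin"], 0.8)
        layers["ARPC2"] = gaussian_filter(layers["ARPC2"], 0.8)

    if not layers:
        raise ConfigError("config enables no image content (nuclei/neurites/coloc)")

    # ---- illumination gradient, background and noise
    grad_amp = float(icfg.get("illumination_gradient", 0.0))
    rows = (np.arange(h) - h / 2) / h
    cols = (np.arange(w) - w / 2) / w
    gradient = 1.0 + grad_amp * (rows[:, None] + cols[None, :]) / 2.0
    noise_sd = float(icfg.get("noise_sd", 0.0))
    names = sorted(layers)
    pixels = np.zeros((len(names), h, w))
    for i, name in enumerate(names):
        chan = (layers[name] + background) * gradient
        if noise_sd > 0:
            chan = chan + rng.normal(0, noise_sd, size=(h, w))
        pixels[i] = np.clip(chan, 0, None)
    img = FieldImage(pixels, {n: i for i, n in enumerate(names)}, pixel_size)
    return img, truth


# ---------------------------------------------------------------- screens


def _plate_layout(rows, cols, n_dmso, n_positive):
    """Control wells in the leading columns, compounds fill the rest row-wise."""
    all_wells = [well_name(r, c) for r in range(rows) for c in range(cols)]
    # column-major order for controls so they occupy whole leading columns
    colmajor = [well_name(r, c) for c in range(cols) for r in range(rows)]
    dmso = colmajor[:n_dmso]
    positive = colmajor[n_dmso:n_dmso + n_positive]
    taken = set(dmso) | set(positive)
    compound = [wl for wl in all_wells if wl not in taken]
    return dmso, positive, compound


def simulate_screen(cfg: dict, seed: int):
    """Simulate a duplicate compound screen as a long well table.

    Compound effects are a latent per-compound shift shared across
    replicates plus independent well noise; actives shift Ki67 up and
    HuC/D down; toxics get low nuclei counts; a per-plate additive jitter
    is applied before any normalization sees the data.
    """
    scfg = cfg["screen_sim"]
    rng = rng_for(seed, "screen")
    n_comp = int(scfg["n_compounds"])
    n_rep = int(scfg["n_replicates"])
    rows, cols = int(scfg["plate"].get("rows", 16)), int(scfg["plate"].get("cols", 24))
    n_dmso, n_pos = int(scfg["plate"]["n_dmso"]), int(scfg["plate"]["n_positive"])
    dmso_wells, pos_wells, comp_wells = _plate_layout(rows, cols, n_dmso, n_pos)
    per_plate = len(comp_wells)
    if per_plate <= 0:
        raise ConfigError("plate layout leaves no compound wells")

    base = scfg["baseline"]
    ki0, hu0 = float(base["ki67_ratio"]), float(base["hucd_ratio"])
    nuc_mu, nuc_sd = float(base["nuclei_mean"]), float(base["nuclei_sd"])
    sw = float(scfg["well_noise_sd"])
    jitter_sd = float(scfg.get("plate_jitter_sd", 0.0))
    lat = scfg.get("latent", {})

    compounds = [f"C{i + 1:05d}" for i in range(n_comp)]
    if len(set(compounds)) != n_comp:
        raise ConfigError("duplicate compound ids")
    acfg, tcfg = scfg.get("actives", {}), scfg.get("toxics", {})
    n_act, n_tox = int(acfg.get("n", 0)), int(tcfg.get("n", 0))
    special = rng.choice(n_comp, size=n_act + n_tox, replace=False)
    active_idx, toxic_idx = special[:n_act], special[n_act:]
    if set(active_idx) & set(toxic_idx):
        raise ConfigError("active and toxic sets must be disjoint")

    # latent effects in well-SD units, shared across replicates
    g = rng.normal(0.0, float(lat.get("shared_sd", 0.0)), n_comp)
    e1 = rng.normal(0.0, float(lat.get("independent_sd", 0.0)), n_comp)
    e2 = rng.normal(0.0, float(lat.get("independent_sd", 0.0)), n_comp)
    lat_ki = g + e1
    lat_hu = float(lat.get("hucd_scale", 1.0)) * g + e2
    for idx, block in ((active_idx, acfg), (toxic_idx, tcfg)):
        if len(idx):
            a = rng.uniform(float(block["effect_min_sd"]), float(block["effect_max_sd"]), len(idx))
            lat_ki[idx] = a
            lat_hu[idx] = -a
    nuc_mean = np.full(n_comp, nuc_mu)
    nuc_s = np.full(n_comp, nuc_sd)
    if len(toxic_idx):
        nuc_mean[toxic_idx] = float(tcfg["nuclei_mean"])
        nuc_s[toxic_idx] = float(tcfg.get("nuclei_sd", nuc_sd))

    pcfg = scfg["positive_control"]
    pos_ki = ki0 + float(pcfg["ki67_shift_sd"]) * sw
    pos_hu = hu0 + float(pcfg["hucd_shift_sd"]) * sw

    n_plates = math.ceil(n_comp / per_plate)
    recs = []
    for rep in range(1, n_rep + 1):
        order = np.arange(n_comp)  # same physical layout each replicate run
        for p in range(n_plates):
            plate_id = f"R{rep}_P{p + 1:03d}"
            jit = rng.normal(0.0, jitter_sd) if jitter_sd > 0 else 0.0
            chunk = order[p * per_plate:(p + 1) * per_plate]

            def emit(well, role, comp_i=None):
                if comp_i is None:
                    ki_mu, hu_mu = (pos_ki, pos_hu) if role == WellRole.POSITIVE else (ki0, hu0)
                    nm, ns = nuc_mu, nuc_sd
                    comp_name, dose = ("GSK-25", 1.0) if role == WellRole.POSITIVE else ("DMSO", None)
                else:
                    ki_mu = ki0 + lat_ki[comp_i] * sw
                    hu_mu = hu0 + lat_hu[comp_i] * sw
                    nm, ns = nuc_mean[comp_i], nuc_s[comp_i]
                    comp_name, dose = compounds[comp_i], 1.0
                recs.append((
                    plate_id, well, comp_name, dose, role, rep,
                    float(np.clip(ki_mu + jit + rng.normal(0, sw), 0, 1)),
                    float(np.clip(hu_mu + jit + rng.normal(0, sw), 0, 1)),
                    int(max(0, round(rng.normal(nm, ns)))),
                ))

            for wl in dmso_wells:
                emit(wl, WellRole.DMSO)
            for wl in pos_wells:
                emit(wl, WellRole.POSITIVE)
            for wl, ci in zip(comp_wells, chunk):
                emit(wl, WellRole.COMPOUND, ci)

    table = pd.DataFrame(
        recs,
        columns=["plate", "well", "compound", "dose", "role", "replicate",
                 "ki67_ratio", "hucd_ratio", "nuclei_count"],
    )
    truth = ScreenTruth(
        active_ids=sorted(compounds[i] for i in active_idx),
        toxic_ids=sorted(compounds[i] for i in toxic_idx),
        latent_ki67={compounds[i]: float(lat_ki[i]) for i in range(n_comp)},
        latent_hucd={compounds[i]: float(lat_hu[i]) for i in range(n_comp)},
    )
    return table, truth


# ------------------------------------------------------------- dose response


def simulate_dose_response(cfg: dict, seed: int):
    """Simulate a two-cell-line dose-response set with labeled specificity.

    Responses follow 4-parameter logistic curves in log dose with additive
    noise. Compound classes: ``prolif_specific`` respond (Ki67 up) only in
    the mutant line — a labeled subset is also HuC/D-specific;
    ``active_both`` respond in both lines; ``flat`` do not respond. Some
    compounds are toxic at the top dose (depressed nuclei counts).
    """
    dcfg = cfg["dose_sim"]
    rng = rng_for(seed, "dose")
    doses = np.asarray(dcfg["doses_um"], dtype=float)
    if np.any(doses <= 0):
        raise ConfigError("doses must be positive")
    n_rep = int(dcfg.get("n_replicates", 3))
    noise = float(dcfg.get("noise_sd", 0.01))
    hill = float(dcfg.get("hill", 1.2))
    ec50 = float(dcfg.get("ec50_um", 0.4))
    amp_ki = float(dcfg["amplitude"]["ki67"])
    amp_hu = float(dcfg["amplitude"]["hucd"])
    nuc_mu, nuc_sd = float(dcfg.get("nuclei_mean", 4000)), float(dcfg.get("nuclei_sd", 250))

    comp = dcfg["compounds"]
    n_spec = int(comp["n_prolif_specific"])
    n_both_spec = int(comp["n_both_specific"])
    n_active = int(comp["n_active_both_lines"])
    n_flat = int(comp["n_flat"])
    n_total = n_spec + n_active + n_flat
    if int(comp.get("n_total", n_total)) != n_total:
        raise ConfigError("compound class counts do not add up to n_total")
    names = [f"D{i + 1:03d}" for i in range(n_total)]
    classes = (["prolif_specific"] * n_spec + ["active_both"] * n_active + ["flat"] * n_flat)
    diff_specific = set(names[:n_both_spec])
    toxic_top = set(
        names[n_spec:n_spec + int(comp.get("n_toxic_top_dose", 0))]
    )  # drawn from the active_both block

    baselines = {
        str(dcfg["mutant_line"]): (float(dcfg["baseline"]["ki67"]), float(dcfg["baseline"]["hucd"])),
        str(dcfg["control_line"]): (float(dcfg["control_baseline"]["ki67"]),
                                    float(dcfg["control_baseline"]["hucd"])),
    }
    mutant = str(dcfg["mutant_line"])

    def logistic(amp):
        return amp / (1.0 + (ec50 / doses) ** hill)

    recs = []
    for name, cls in zip(names, classes):
        for line, (ki0, hu0) in baselines.items():
            ki = np.full_like(doses, ki0)
            hu = np.full_like(doses, hu0)
            if cls == "active_both":
                ki = ki + logistic(amp_ki)
                hu = hu + logistic(amp_hu)
            elif cls == "prolif_specific":
                if line == mutant:
                    ki = ki + logistic(amp_ki)
                    hu = hu + logistic(amp_hu)
                elif name not in diff_specific:
                    hu = hu + logistic(amp_hu)  # HuC/D response in both lines
            for rep in range(1, n_rep + 1):
                for j, d in enumerate(doses):
                    toxic_here = name in toxic_top and j == int(np.argmax(doses))
                    nuc = rng.normal(1200.0, 150.0) if toxic_here else rng.normal(nuc_mu, nuc_sd)
                    recs.append((
                        name, cls, line, float(d), rep,
                        float(np.clip(ki[j] + rng.normal(0, noise), 0, 1)),
                        float(np.clip(hu[j] + rng.normal(0, noise), 0, 1)),
                        int(max(0, round(nuc))),
                    ))
    table = pd.DataFrame(
        recs,
        columns=["compound", "class", "cell_line", "dose_um", "replicate",
                 "ki67_ratio", "hucd_ratio", "nuclei_count"],
    )
    truth = {
        "prolif_specific": [n for n, c in zip(names, classes) if c == "prolif_specific"],
        "diff_specific": sorted(diff_specific),
        "toxic_top_dose": sorted(toxic_top),
    }
    return table, truth


# --------------------------------------------------------------- spike trains


def simulate_spike_trains(cfg: dict, condition: str, seed: int):
    """Simulate one MEA well of spike trains under a named condition.

    Plain conditions are homogeneous Poisson at the condition rate; with a
    ``burst`` block, Poisson burst onsets carry high-rate intra-burst
    spiking on top of a tonic rate. Pairwise correlation is induced by
    thinning a shared mother process with probability rho (the pairwise
    count correlation equals rho), followed by a small timing jitter.
    """
    mcfg = cfg["mea_sim"]
    cond = _condition_block(cfg, condition)
    rng = rng_for(seed, f"mea:{condition}")
    n_elec = int(mcfg["n_electrodes"])
    duration = float(mcfg["duration_s"])
    if duration <= 0:
        raise ConfigError("duration_s must be positive")
    rho = float(cond.get("rho", 0.0))
    if not 0.0 <= rho <= 1.0:
        raise ConfigError("rho must be in [0, 1]")
    jitter_s = float(mcfg.get("jitter_ms", 0.0)) / 1000.0
    burst = cond.get("burst")

    def poisson_times(rate):
        n = rng.poisson(rate * duration)
        return np.sort(rng.uniform(0.0, duration, n))

    electrodes = {}
    if burst:
        tonic = float(burst.get("tonic_rate_hz", 0.0))
        b_rate = float(burst["burst_rate_hz"])
        b_len = float(burst["length_s"])
        intra = float(burst["intra_rate_hz"])
        for i in range(n_elec):
            onsets = poisson_times(b_rate)
            t = [poisson_times(tonic)] if tonic > 0 else []
            for t0 in onsets:
                k = rng.poisson(intra * b_len)
                t.append(t0 + np.sort(rng.uniform(0.0, b_len, k)))
            times = np.sort(np.concatenate(t)) if t else np.empty(0)
            electrodes[f"E{i + 1:02d}"] = np.unique(times[times <= duration])
        rates = {e: len(t) / duration for e, t in electrodes.items()}
    else:
        rate = float(cond["rate_hz"])
        if rate < 0:
            raise ConfigError("rate_hz must be non-negative")
        if rho > 0 and rate > 0:
            mother = poisson_times(rate / rho)
            for i in range(n_elec):
                keep = mother[rng.random(mother.size) < rho]
                if jitter_s > 0:
                    keep = keep + rng.normal(0.0, jitter_s, keep.size)
                keep = keep[(keep >= 0) & (keep <= duration)]
                electrodes[f"E{i + 1:02d}"] = np.unique(keep)
        else:
            for i in range(n_elec):
                electrodes[f"E{i + 1:02d}"] = poisson_times(rate)
        rates = {e: float(cond["rate_hz"]) for e in electrodes}

    trains = SpikeTrainSet(electrodes, duration, well_id=condition)
    return trains, MEATruth(rates_hz=rates, rho=rho)


def synthesize_voltage_trace(spike_times, duration_s, sampling_hz, noise_sd,
                             amplitude_sd_units, seed=0):
    """White-noise voltage trace with negative-going spikes at given times.

    Spike amplitude is expressed in units of the noise SD; the waveform is
    a brief biphasic transient (sharp trough, small rebound).
    """
    rng = rng_for(seed, "voltage")
    n = int(round(duration_s * sampling_hz))
    trace = rng.normal(0.0, noise_sd, n)
    # ~1.2 ms biphasic waveform sampled at the trace rate
    wlen = max(8, int(0.0012 * sampling_hz))
    tt = np.linspace(0, 1, wlen)
    wave = -np.exp(-((tt - 0.3) ** 2) / 0.03) + 0.3 * np.exp(-((tt - 0.75) ** 2) / 0.03)
    wave *= amplitude_sd_units * noise_sd / np.abs(wave).max()
    for t in np.asarray(spike_times, dtype=float):
        i = int(round(t * sampling_hz))
        j = min(n, i + wlen)
        if i < n:
            trace[i:j] += wave[: j - i]
    return trace
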