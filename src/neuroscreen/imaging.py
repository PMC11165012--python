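"""Per-field phenotypic feature extraction.

Implements the imaging readouts of the screen: illumination correction,
nuclei segmentation into live/dead/debris with Ki67/HuC-D positivity
scoring (a nucleus is positive when over 5% / over 50% of its area
overlaps the marker segmentation, strict inequalities), MAP2 neurite
skeletonization, synaptic punctum detection, synapse calling by triple
colocalization (Synapsin1 + SHANK3 + skeleton), two-channel area-overlap
colocalization, and per-well aggregation as unweighted means over fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.feature import peak_local_max
from skimage.morphology import disk, skeletonize
from skimage.segmentation import watershed

from .core import FieldImage

KI67_OVERLAP_MIN = 0.05  # strict: > 5% of the nucleus area
HUCD_OVERLAP_MIN = 0.50  # strict: > 50% of the nucleus area

DEFAULT_SEGMENTATION = {
    "debris_area_frac": 0.25,       # debris: area < frac x median live area
    "dead_area_frac": 0.60,         # dead: smaller AND brighter than live
    "dead_intensity_factor": 1.5,
    "min_area_px": 8,
    "watershed_min_distance": 7,
    "distance_smooth_px": 2.0,  # smooths the distance map before peak finding
}

DEFAULT_PUNCTA = {
    "sigma_px": 1.8,
    "snr_min": 5.0,
    "area_min_px": 3,
    "area_max_px": 200,
    "intensity_min": 40.0,
    "min_separation_px": 3,
    "peak_threshold_sd": 4.0,   # DoG peak scan threshold, robust SDs
}


@dataclass
class NucleusRecord:
    label: int
    area_px: int
    centroid: tuple
    mean_nuclear_intensity: float
    cls: str  # live | dead | debris
    ki67_overlap_frac: float = float("nan")
    hucd_overlap_frac: float = float("nan")
    ki67_positive: bool | None = None
    hucd_positive: bool | None = None


@dataclass
class SkeletonGraph:
    mask: np.ndarray  # 1-px-wide boolean skeleton
    total_length_um: float
    pixel_size_um: float


@dataclass
class Punctum:
    channel: str
    centroid: tuple
    area_px: int
    peak_intensity: float
    integrated_intensity: float
    snr: float
    on_skeleton: bool = False


@dataclass
class Synapse:
    synapsin: Punctum
    shank3: Punctum
    distance_px: float

    @property
    def shank3_integrated_intensity(self) -> float:
        return self.shank3.integrated_intensity


@dataclass
class WellFeatures:
    """Per-well features: unweighted means over the well's usable fields."""

    n_live: float = float("nan")
    n_dead: float = float("nan")
    n_debris: float = float("nan")
    ki67_ratio: float = float("nan")
    hucd_ratio: float = float("nan")
    neurite_length_um: float = float("nan")
    n_synapsin: float = float("nan")
    n_shank3: float = float("nan")
    n_synapses: float = float("nan")
    synaptic_shank3_intensity: float = float("nan")
    coloc_fraction: float = float("nan")
    n_fields_used: dict = field(default_factory=dict)


# ------------------------------------------------------------ thresholds


def _robust_stats(chan: np.ndarray):
    med = float(np.median(chan))
    mad = float(np.median(np.abs(chan - med)))
    return med, 1.4826 * mad


def auto_threshold(chan: np.ndarray, override: float | None = None):
    """Per-image foreground threshold: Otsu floored at median + 3 robust SD.

    The floor keeps signal-free channels (e.g. a marker nobody expresses)
    from being split into spurious foreground by Otsu. Returns ``None``
    when the channel has no resolvable foreground.
    """
    if override is not None:
        return float(override)
    med, rsd = _robust_stats(chan)
    if chan.max() <= med + 3 * rsd + 1e-12:
        return None
    try:
        t = float(threshold_otsu(chan))
    except ValueError:
        return None
    return max(t, med + 3 * rsd)


# --------------------------------------------------- illumination correction


def _polynomial_background(chan: np.ndarray, order: int = 2, step: int = 4) -> np.ndarray:
    """Least-squares order-2 surface fitted on a subsampled grid."""
    h, w = chan.shape
    rr, cc = np.mgrid[0:h:step, 0:w:step]
    y = chan[::step, ::step].ravel()
    r = rr.ravel() / h
    c = cc.ravel() / w
    terms = [np.ones_like(r), r, c]
    if order >= 2:
        terms += [r * r, r * c, c * c]
    A = np.stack(terms, axis=1)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    rf, cf = np.mgrid[0:h, 0:w]
    rf = rf / h
    cf = cf / w
    full = [np.ones_like(rf), rf, cf]
    if order >= 2:
        full += [rf * rf, rf * cf, cf * cf]
    return sum(k * t for k, t in zip(coef, full))


def correct_illumination(img: FieldImage, sigma_px: float | None = None,
                         method: str = "polynomial") -> FieldImage:
    """Remove smooth multiplicative illumination, preserving channel means.

    Each channel is divided by a smooth background estimate: by default a
    least-squares quadratic surface (exact for linear/quadratic gradients
    out to the field edges), or a heavily Gaussian-blurred copy
    (``method='gaussian'``; ``sigma_px`` defaults to a quarter of the
    image width). Flat channels are unchanged up to numerical tolerance;
    all-zero channels are returned as-is.
    """
    if sigma_px is None:
        sigma_px = img.shape[1] / 4.0
    if sigma_px <= 0:
        raise ValueError("sigma_px must be positive")
    out = np.empty_like(img.pixels, dtype=float)
    for i in range(img.pixels.shape[0]):
        chan = img.pixels[i].astype(float)
        mean = chan.mean()
        if mean == 0:
            out[i] = chan
            continue
        if method == "polynomial":
            bg = _polynomial_background(chan)
        elif method == "gaussian":
            bg = ndi.gaussian_filter(chan, sigma_px)
        else:
            raise ValueError(f"unknown illumination method {method!r}")
        eps = 1e-6 * max(float(bg.max()), 1.0)
        flat = chan / np.maximum(bg, eps)
        out[i] = flat * (mean / flat.mean())
    return img.with_pixels(out)


# ------------------------------------------------------- nuclei segmentation


def segment_nuclei(img: FieldImage, thresholds: dict | None = None,
                   nuclear_channel: str = "Hoechst"):
    """Segment the nuclear channel into labelled nuclei and classify them.

    Threshold -> fill -> distance-transform watershed to split touching
    nuclei -> size/intensity classification into debris, dead and live.
    Returns ``(records, label_image)``; an empty image yields ``([], zeros)``.
    """
    cfg = {**DEFAULT_SEGMENTATION, **(thresholds or {})}
    chan = img.channel(nuclear_channel).astype(float)
    t = auto_threshold(chan, cfg.get("nuclear_threshold"))
    labels = np.zeros(chan.shape, dtype=np.int32)
    if t is None:
        return [], labels
    mask = ndi.binary_fill_holes(chan > t)
    if not mask.any():
        return [], labels
    dist = ndi.distance_transform_edt(mask)
    smooth = ndi.gaussian_filter(dist, float(cfg["distance_smooth_px"]))
    peaks = peak_local_max(smooth, min_distance=int(cfg["watershed_min_distance"]),
                           labels=mask, exclude_border=False)
    markers = np.zeros(chan.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        labels, _ = ndi.label(mask)
    else:
        labels = watershed(-dist, markers, mask=mask)

    objs = ndi.find_objects(labels)
    areas, intensities, labs = [], [], []
    for lab, sl in enumerate(objs, start=1):
        if sl is None:
            continue
        m = labels[sl] == lab
        area = int(m.sum())
        if area < int(cfg["min_area_px"]):
            labels[sl][m] = 0
            continue
        labs.append(lab)
        areas.append(area)
        intensities.append(float(chan[sl][m].mean()))
    if not labs:
        return [], labels
    areas = np.asarray(areas, float)
    intensities = np.asarray(intensities, float)

    # reference live population: objects at least dead-sized, by area
    med0 = float(np.median(areas))
    ref = areas >= cfg["dead_area_frac"] * med0
    if not ref.any():
        ref = np.ones_like(areas, bool)
    live_med_area = float(np.median(areas[ref]))
    live_med_int = float(np.median(intensities[ref]))

    records = []
    coms = ndi.center_of_mass(np.ones_like(labels), labels, labs)
    for lab, area, inten, com in zip(labs, areas, intensities, coms):
        if area < cfg["debris_area_frac"] * live_med_area:
            cls = "debris"
        elif (area < cfg["dead_area_frac"] * live_med_area
              and inten > cfg["dead_intensity_factor"] * live_med_int):
            cls = "dead"
        else:
            cls = "live"
        records.append(NucleusRecord(int(lab), int(area), tuple(com), inten, cls))
    return records, labels


def score_marker_positivity(nuclei, labels: np.ndarray, img: FieldImage,
                            thresholds: dict | None = None):
    """Score Ki67/HuC-D positivity by nucleus-mask overlap fractions.

    Positivity is strict: Ki67 if > 5%, HuC/D if > 50% of the nucleus area
    overlaps the marker segmentation. Missing marker channels leave the
    corresponding fields unset. Debris are scored but excluded from ratios
    downstream.
    """
    thresholds = thresholds or {}
    markers = {
        "ki67": ("Ki67", KI67_OVERLAP_MIN),
        "hucd": ("HuCD", HUCD_OVERLAP_MIN),
    }
    for key, (chan_name, cutoff) in markers.items():
        if not img.has_channel(chan_name):
            continue
        chan = img.channel(chan_name).astype(float)
        t = auto_threshold(chan, thresholds.get(f"{key}_threshold"))
        mask = chan > t if t is not None else np.zeros(chan.shape, bool)
        for rec in nuclei:
            nmask = labels == rec.label
            overlap = float((mask & nmask).sum()) / max(rec.area_px, 1)
            setattr(rec, f"{key}_overlap_frac", overlap)
            setattr(rec, f"{key}_positive", bool(overlap > cutoff))
    return nuclei


def compute_ratios(nuclei):
    """Marker-positive ratios over live nuclei; undefined (NaN) with 0 live."""
    live = [n for n in nuclei if n.cls == "live"]
    n_dead = sum(1 for n in nuclei if n.cls == "dead")
    n_debris = sum(1 for n in nuclei if n.cls == "debris")
    if not live:
        return float("nan"), float("nan"), 0, n_dead, n_debris

    def ratio(attr):
        vals = [getattr(n, attr) for n in live]
        if all(v is None for v in vals):
            return float("nan")
        return sum(bool(v) for v in vals) / len(live)

    return ratio("ki67_positive"), ratio("hucd_positive"), len(live), n_dead, n_debris


# ------------------------------------------------------------- skeleton


def _skeleton_length_px(skel: np.ndarray) -> float:
    """Inter-pixel step length: 1 per 4-adjacency, sqrt(2) per strict diagonal.

    A diagonal pair is counted only when neither of its two common
    4-neighbours is set, so staircase corners are not double counted.
    """
    s = skel.astype(bool)
    n4 = int((s[:, 1:] & s[:, :-1]).sum()) + int((s[1:, :] & s[:-1, :]).sum())
    d1 = s[1:, 1:] & s[:-1, :-1] & ~s[1:, :-1] & ~s[:-1, 1:]
    d2 = s[1:, :-1] & s[:-1, 1:] & ~s[1:, 1:] & ~s[:-1, :-1]
    return n4 + math.sqrt(2.0) * (int(d1.sum()) + int(d2.sum()))


def _prune_spurs(skel: np.ndarray, min_len: int) -> np.ndarray:
    """Remove endpoint branches shorter than ``min_len`` pixels."""
    s = skel.copy()
    kernel = np.ones((3, 3), int)
    for _ in range(2):  # two passes handle spurs revealed by the first
        nb = ndi.convolve(s.astype(int), kernel, mode="constant") - s
        endpoints = np.argwhere(s & (nb == 1))
        removed = False
        for r, c in endpoints:
            path = [(r, c)]
            prev = None
            cur = (int(r), int(c))
            while len(path) <= min_len:
                neigh = [
                    (cur[0] + dr, cur[1] + dc)
                    for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                    if (dr or dc)
                    and 0 <= cur[0] + dr < s.shape[0] and 0 <= cur[1] + dc < s.shape[1]
                    and s[cur[0] + dr, cur[1] + dc] and (cur[0] + dr, cur[1] + dc) != prev
                ]
                if len(neigh) != 1:
                    break  # junction (or isolated point): stop walking
                prev, cur = cur, neigh[0]
                path.append(cur)
            else:
                continue  # branch longer than min_len: keep
            if len(neigh) > 1:  # ended at a junction: prune the spur
                for p in path[:-1] if path[-1] == cur else path:
                    s[p] = False
                removed = True
        if not removed:
            break
    return s


def skeletonize_neurites(img: FieldImage, threshold: float | None = None,
                         closing_px: int = 2, spur_min_px: int = 8) -> SkeletonGraph:
    """Threshold the MAP2 channel, close, thin to 1 px and measure length."""
    chan = img.channel("MAP2").astype(float)
    t = auto_threshold(chan, threshold)
    if t is None:
        return SkeletonGraph(np.zeros(chan.shape, bool), 0.0, img.pixel_size_um)
    mask = chan > t
    if closing_px > 0:
        mask = ndi.binary_closing(mask, structure=disk(closing_px))
    skel = skeletonize(mask)
    if spur_min_px > 0:
        skel = _prune_spurs(skel, spur_min_px)
    length_um = _skeleton_length_px(skel) * img.pixel_size_um
    return SkeletonGraph(skel, length_um, img.pixel_size_um)


# --------------------------------------------------------------- puncta


def detect_puncta(img: FieldImage, channel: str, params: dict | None = None):
    """Detect punctate spots: DoG band-pass, local maxima, half-max growth,
    then SNR / area / intensity filtering.

    SNR is (peak - local background median) / robust background SD, with
    the background taken from an annulus between 2x and 4x the spot sigma.
    """
    p = {**DEFAULT_PUNCTA, **(params or {})}
    chan = img.channel(channel).astype(float)
    sigma = float(p["sigma_px"])
    dog = ndi.gaussian_filter(chan, sigma) - ndi.gaussian_filter(chan, 2 * sigma)
    med, rsd = _robust_stats(dog)
    peaks = peak_local_max(dog, min_distance=int(p["min_separation_px"]),
                           threshold_abs=med + float(p["peak_threshold_sd"]) * max(rsd, 1e-9),
                           exclude_border=False)
    h, w = chan.shape
    inner, outer = 2 * sigma, 4 * sigma
    rad = int(math.ceil(outer))
    out = []
    for r, c in peaks:
        r0, r1 = max(0, r - rad), min(h, r + rad + 1)
        c0, c1 = max(0, c - rad), min(w, c + rad + 1)
        win = chan[r0:r1, c0:c1]
        rr, cc = np.mgrid[r0:r1, c0:c1]
        d = np.hypot(rr - r, cc - c)
        ann = win[(d >= inner) & (d <= outer)]
        if ann.size < 8:
            continue
        bg_med = float(np.median(ann))
        bg_sd = 1.4826 * float(np.median(np.abs(ann - bg_med)))
        peak_val = float(chan[r, c])
        amp = peak_val - bg_med
        snr = amp / max(bg_sd, 1e-9)
        # region grown at half-max around the peak
        grow = (win - bg_med) >= amp / 2.0
        lab, _ = ndi.label(grow)
        region = lab == lab[r - r0, c - c0]
        area = int(region.sum())
        if snr < p["snr_min"] or not (p["area_min_px"] <= area <= p["area_max_px"]):
            continue
        if amp < p["intensity_min"]:
            continue
        weights = np.where(region, win - bg_med, 0.0)
        total = weights.sum()
        centroid = (float((rr * weights).sum() / total), float((cc * weights).sum() / total))
        out.append(Punctum(channel, centroid, area, peak_val, float(total), snr))
    return out


def call_synapses(synapsin, shank3, skel: SkeletonGraph,
                  pairing_radius_px: float = 6.0, skel_dilation_px: int = 2):
    """Triple colocalization: both puncta on the dilated skeleton and within
    the pairing radius; greedy one-to-one matching by ascending distance,
    ties broken by the Synapsin1 centroid (row, col)."""
    dil = ndi.binary_dilation(skel.mask, structure=disk(skel_dilation_px)) \
        if skel.mask.any() else skel.mask
    h, w = dil.shape

    def mark(puncta):
        kept = []
        for p in puncta:
            r, c = int(round(p.centroid[0])), int(round(p.centroid[1]))
            p.on_skeleton = bool(0 <= r < h and 0 <= c < w and dil[r, c])
            if p.on_skeleton:
                kept.append(p)
        return kept

    syn_on, sh_on = mark(synapsin), mark(shank3)
    cand = []
    for i, a in enumerate(syn_on):
        for j, b in enumerate(sh_on):
            d = math.hypot(a.centroid[0] - b.centroid[0], a.centroid[1] - b.centroid[1])
            if d <= pairing_radius_px:
                cand.append((d, a.centroid[0], a.centroid[1], i, j))
    cand.sort()
    used_a, used_b = set(), set()
    synapses = []
    for d, _, _, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        synapses.append(Synapse(syn_on[i], sh_on[j], d))
    return synapses


# ----------------------------------------------------------- colocalization


def coloc_fraction(img: FieldImage, channel_a: str, channel_b: str,
                   thresholds: dict | None = None) -> float:
    """Fraction of channel-A-positive area overlapping channel B (|A∩B|/|A|).

    Returns NaN when channel A has no positive area.
    """
    thresholds = thresholds or {}
    masks = {}
    for name in (channel_a, channel_b):
        chan = img.channel(name).astype(float)
        t = auto_threshold(chan, thresholds.get(name))
        masks[name] = chan > t if t is not None else np.zeros(chan.shape, bool)
    a_area = int(masks[channel_a].sum())
    if a_area == 0:
        return float("nan")
    return float((masks[channel_a] & masks[channel_b]).sum()) / a_area


# --------------------------------------------------------------- aggregation

_WELL_FEATURES = [
    "n_live", "n_dead", "n_debris", "ki67_ratio", "hucd_ratio",
    "neurite_length_um", "n_synapsin", "n_shank3", "n_synapses",
    "synaptic_shank3_intensity", "coloc_fraction",
]


def aggregate_well(field_results: list) -> WellFeatures:
    """Unweighted mean over fields for every feature.

    ``field_results`` is a list of per-field dicts; fields with an
    undefined (NaN/absent) value are excluded from that feature's mean,
    and the per-feature count of usable fields is recorded. A well with no
    usable field for any feature comes back all-NaN.
    """
    wf = WellFeatures()
    for name in _WELL_FEATURES:
        vals = [fr[name] for fr in field_results
                if name in fr and fr[name] is not None and not np.isnan(fr[name])]
        wf.n_fields_used[name] = len(vals)
        if vals:
            setattr(wf, name, float(np.mean(vals)))
    return wf
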