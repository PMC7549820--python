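"""Informed + agnostic feature dictionary for MEA recordings.

The informed entries are electrophysiological biomarkers (Fig.-style
FP markers: depolarization amplitude DA, field-potential duration FPD,
repolarization center RC, notch FPN, repolarization amplitude RA,
width RW and area AUCr; calcium markers CA, DC, CDX), expressed as
drug/control ratios, plus five repolarization-distortion markers K1-K5
comparing the drug and control repolarization waves. The agnostic
entries are discrete-wavelet coefficients of |drug - control| over the
plateau + repolarization phases, at coefficient positions selected on
the training set by hard thresholding.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pywt

from .signals import TimeSignal

logger = logging.getLogger(__name__)

FP_MARKERS = ("da", "fpd", "rc", "fpn", "auc_r", "ra", "rw")
CA_MARKERS = ("ca", "dc", "cdx")
K_MARKERS = ("k1", "k2", "k3", "k4", "k5")


class QuiescentSignalError(ValueError):
    """Raised when a trace carries no usable beat (quiescent/noisy well)."""


@dataclass(frozen=True)
class SegmentConfig:
    """Beat segmentation settings (all thresholds are config keys)."""

    spike_mad_factor: float = 5.0     # spike detection threshold, x MAD
    depol_halfwidth: float = 25.0     # ms around the spike
    notch_len: float = 50.0           # ms after the depol window for FPN
    repol_min_delay: float = 50.0     # ms after depol end before RC search
    repol_end_fraction: float = 0.1   # wave end at this fraction of RA
    repol_start_fraction: float = 0.5 # plateau/repol boundary fraction
    repol_smooth: float = 25.0        # ms smoothing before peak search


@dataclass(frozen=True)
class Window:
    """Half-open time window [start, end] in trace time units (ms)."""

    start: float
    end: float

    @property
    def span(self) -> float:
        return self.end - self.start


def _baseline(values: np.ndarray, n_low: float = 0.3) -> float:
    k = max(1, int(round(n_low * values.size)))
    return float(np.median(np.sort(values)[:k]))


def segment_fp(trace: TimeSignal, config: SegmentConfig | None = None):
    """Split one FP beat into depolarization, plateau and repolarization.

    The depolarization window is centred on the max |dV/dt| spike; the
    repolarization window runs from the end of the depolarization
    window to the end of the detected repolarization wave. Raises
    QuiescentSignalError when no spike rises above the noise floor.
    """
    cfg = config or SegmentConfig()
    v = trace.values
    t = trace.times
    dv = np.abs(np.diff(v))
    med = np.median(dv)
    mad = np.median(np.abs(dv - med)) + 1e-30
    i_spike = int(np.argmax(dv))
    if dv[i_spike] < med + cfg.spike_mad_factor * mad or dv[i_spike] <= 0:
        raise QuiescentSignalError("no depolarization spike above noise floor")
    t_spike = t[i_spike]
    depol = Window(max(t[0], t_spike - cfg.depol_halfwidth),
                   min(t[-1], t_spike + cfg.depol_halfwidth))

    pre = v[t < depol.start]
    baseline = float(np.median(pre)) if pre.size >= 5 else float(np.median(v))
    i_rc, ra, _, _ = _repol_peak(v, t, baseline, depol, cfg)
    dev = np.abs(v - baseline)
    after = np.where((t > t[i_rc]) & (dev <= cfg.repol_end_fraction * ra))[0]
    t_end = t[after[0]] if after.size else t[-1]
    before = np.where((t > depol.end) & (t < t[i_rc])
                      & (dev <= cfg.repol_start_fraction * ra))[0]
    t_repol_start = t[before[-1]] if before.size else depol.end
    plateau = Window(depol.end, max(depol.end, t_repol_start))
    repol = Window(depol.end, t_end)
    return depol, plateau, repol


def _repol_peak(v, t, baseline, depol: Window, cfg: SegmentConfig):
    """Locate the repolarization wave after the depolarization spike.

    Works on the smoothed absolute deviation from baseline; the wave is
    the most prominent local peak in the search window, which is robust
    to the slow decay tail the electrode RC circuit leaves after the
    spike. Falls back to the absolute maximum when no local peak
    exists (clean monotone-tail-free signals).

    Returns (index of RC, RA, half-height left index, right index).
    """
    from scipy.signal import find_peaks
    dt = float(t[1] - t[0])
    dev = np.abs(v - baseline)
    n_smooth = max(1, int(round(cfg.repol_smooth / dt)))
    kernel = np.ones(n_smooth) / n_smooth
    smooth = np.convolve(dev, kernel, mode="same")
    n_fine = max(1, int(round(5.0 / dt)))
    fine = np.convolve(dev, np.ones(n_fine) / n_fine, mode="same")
    search_from = min(depol.end + cfg.repol_min_delay, t[-1])
    mask = t >= search_from
    if mask.sum() < 3:
        raise QuiescentSignalError("trace ends before repolarization")
    region = np.where(mask)[0]
    seg = smooth[region]
    # noise floor from the high-frequency residual (robust to waves and
    # to short pre-spike baselines), scaled to the smoothing window
    resid = dev - fine
    noise_raw = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    noise_sd = noise_raw / math.sqrt(n_smooth)
    prom_min = max(6.0 * noise_sd, 0.1 * seg.max())
    peaks, props = find_peaks(seg, prominence=prom_min)
    if peaks.size:
        # distinct repolarization wave: its most prominent peak
        best = int(np.argmax(props["prominences"]))
        i_rc = int(region[peaks[best]])
    else:
        # no distinct wave (wave merged with the post-spike plateau):
        # take the falling-edge midpoint of the plateau as the center
        i_max = int(np.argmax(seg))
        tail = seg[i_max:]
        half_level = 0.5 * (seg[i_max] + tail.min())
        below = np.where(tail <= half_level)[0]
        i_rc = int(region[i_max + (below[0] if below.size else tail.size - 1)])
    ra = float(fine[i_rc])
    half = 0.5 * ra
    left = i_rc
    while left > region[0] and fine[left] > half:
        left -= 1
    right = i_rc
    while right < v.size - 1 and fine[right] > half:
        right += 1
    return i_rc, ra, left, right


@dataclass
class FpBiomarkers:
    da: float       # depolarization amplitude, uV
    fpd: float      # field potential duration, ms
    rc: float       # repolarization center time, ms
    fpn: float      # notch amplitude, uV
    auc_r: float    # area under the repolarization wave, uV*ms
    ra: float       # repolarization amplitude, uV
    rw: float       # repolarization width, ms

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in FP_MARKERS}


def fp_biomarkers(trace: TimeSignal,
                  config: SegmentConfig | None = None) -> FpBiomarkers:
    """Compute the FP biomarker set on one beat.

    DA = max - min inside the depolarization window; RC = time of the
    extremal repolarization deviation; FPD = RC - spike time;
    RA = |value at RC - baseline|; RW = width of the wave at half RA;
    AUCr = integral of |wave - baseline|; FPN = largest deviation in
    the notch window just after the spike.
    """
    cfg = config or SegmentConfig()
    depol, plateau, repol = segment_fp(trace, cfg)
    v = trace.values
    t = trace.times
    dv = np.abs(np.diff(v))
    t_spike = t[int(np.argmax(dv))]
    pre = v[t < depol.start]
    baseline = float(np.median(pre)) if pre.size >= 5 else float(np.median(v))

    in_depol = (t >= depol.start) & (t <= depol.end)
    da = float(v[in_depol].max() - v[in_depol].min())

    in_notch = (t > depol.end) & (t <= depol.end + cfg.notch_len)
    fpn = float(np.abs(v[in_notch] - baseline).max()) if in_notch.any() else 0.0

    i_rc, ra, left, right = _repol_peak(v, t, baseline, depol, cfg)
    rc = float(t[i_rc])
    dev = np.abs(v - baseline)

    in_repol = (t >= repol.start) & (t <= repol.end)
    auc_r = float(np.trapezoid(dev[in_repol], dx=trace.dt))
    rw = float(t[right] - t[left])

    return FpBiomarkers(da=da, fpd=rc - float(t_spike), rc=rc, fpn=fpn,
                        auc_r=auc_r, ra=ra, rw=rw)


@dataclass
class CalciumBiomarkers:
    ca: float     # transient amplitude, uM
    dc: float     # "drowsing calcium": time to 90% recovery, ms
    cdx: float    # duration at X% repolarization, ms

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in CA_MARKERS}


def calcium_biomarkers(trace: TimeSignal, x_percent: float = 90.0,
                       min_amplitude: float = 0.02) -> CalciumBiomarkers:
    """Calcium transient amplitude, decay and duration markers.

    CA = peak - diastolic baseline; CDX = time spent above
    baseline + (1 - X/100) * CA; DC = time from the peak to 90% return
    toward baseline. Raises QuiescentSignalError for flat traces.
    """
    v = trace.values
    t = trace.times
    baseline = _baseline(v)
    i_peak = int(np.argmax(v))
    ca = float(v[i_peak] - baseline)
    if ca < min_amplitude:
        raise QuiescentSignalError("no calcium transient above noise floor")
    level = baseline + (1.0 - x_percent / 100.0) * ca
    cdx = float(np.count_nonzero(v > level) * trace.dt)
    after = np.where((t > t[i_peak]) & (v <= baseline + 0.1 * ca))[0]
    dc = float((t[after[0]] - t[i_peak]) if after.size else t[-1] - t[i_peak])
    return CalciumBiomarkers(ca=ca, dc=dc, cdx=cdx)


def ratio_to_control(drug: dict, ctrl: dict) -> dict:
    """Elementwise drug/control marker ratios.

    A zero control value yields NaN (the undefined-ratio flag); dense
    imputation happens at feature-matrix assembly.
    """
    out = {}
    for key, d in drug.items():
        c = ctrl.get(key)
        if c is None:
            continue
        out[key] = float(d) / float(c) if c != 0 else float("nan")
    return out


@dataclass
class RepolDistortion:
    k1: float   # max squared pointwise distance
    k2: float   # l2 norm of the difference
    k3: float   # average deviation
    k4: float   # max deviation
    k5: float   # time of the max deviation (from window start)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in K_MARKERS}


def _resample_window(sig: TimeSignal, window: Window | None, n: int) -> np.ndarray:
    s = sig if window is None else sig.slice(window.start, window.end)
    t = s.times
    tt = np.linspace(t[0], t[-1], n)
    return np.interp(tt, t, s.values)


def repolarization_markers(drug_rep, ctrl_rep, n_points: int | None = 256,
                           dt: float = 1.0) -> RepolDistortion:
    """Distortion markers between drug and control repolarization waves.

    Inputs are TimeSignals (resampled onto ``n_points`` common points
    spanning each window) or equal-length arrays sampled at ``dt``
    (used as-is when ``n_points`` is None).
    """
    if isinstance(drug_rep, TimeSignal):
        if n_points is None:
            n_points = 256
        span = drug_rep.duration
        d = _resample_window(drug_rep, None, n_points)
        c = _resample_window(ctrl_rep, None, n_points)
        step = span / (n_points - 1)
    else:
        d = np.asarray(drug_rep, dtype=float)
        c = np.asarray(ctrl_rep, dtype=float)
        if n_points is not None and d.size != n_points:
            raise ValueError("array inputs must already have n_points samples")
        if d.shape != c.shape:
            raise ValueError("drug and control windows differ in length")
        step = dt
    diff = d - c
    i_max = int(np.argmax(diff))
    return RepolDistortion(
        k1=float(np.max(diff ** 2)),
        k2=float(np.sqrt(np.sum(diff ** 2))),
        k3=float(np.mean(diff)),
        k4=float(diff[i_max]),
        k5=float(i_max * step),
    )


# ------------------------------------------------------------- wavelets

def _pad_pow2(x: np.ndarray) -> np.ndarray:
    n = 1 << (x.size - 1).bit_length()
    if n == x.size:
        return x
    return np.pad(x, (0, n - x.size))


def _dwt_coeffs(window: np.ndarray, wavelet: str, level: int | None):
    w = pywt.Wavelet(wavelet)
    x = _pad_pow2(np.asarray(window, dtype=float))
    lev = level or pywt.dwt_max_level(x.size, w.dec_len)
    coeffs = pywt.wavedec(x, w, mode="periodization", level=lev)
    arr, slices = pywt.coeffs_to_array(coeffs)
    return arr, slices, w, x.size


def wavelet_positions(training_diffs, thr: float, wavelet: str = "db4",
                      level: int | None = None) -> np.ndarray:
    """Select wavelet-coefficient positions on the training windows.

    For every |drug - control| window, compute the discrete wavelet
    transform, keep positions whose coefficient magnitude exceeds
    ``thr``, and return the sorted union across windows.
    """
    if thr < 0:
        raise ValueError("threshold must be non-negative")
    training_diffs = list(training_diffs)
    if not training_diffs:
        raise ValueError("empty training window list")
    pos: set[int] = set()
    for win in training_diffs:
        arr, _, _, _ = _dwt_coeffs(win, wavelet, level)
        pos.update(np.where(np.abs(arr) > thr)[0].tolist())
    return np.array(sorted(pos), dtype=int)


@dataclass
class WaveletFeatureResult:
    values: np.ndarray            # coefficients at the selected positions
    l2_error: float               # reconstruction error from those positions
    extra_positions: np.ndarray   # refresh hook: positions missing from v_p

    @property
    def needs_refresh(self) -> bool:
        return self.extra_positions.size > 0


def wavelet_features(diff_window, v_p, thr: float = 0.0,
                     l2_tolerance: float = np.inf, wavelet: str = "db4",
                     level: int | None = None) -> WaveletFeatureResult:
    """Wavelet coefficients of a window at pre-selected positions.

    Reconstructs the window from the selected positions only; when the
    L2 reconstruction error exceeds ``l2_tolerance`` the result lists
    the above-threshold positions outside ``v_p`` instead of silently
    degrading (the dictionary-refresh hook).
    """
    v_p = np.asarray(v_p, dtype=int)
    arr, slices, w, n = _dwt_coeffs(diff_window, wavelet, level)
    if v_p.size and (v_p.min() < 0 or v_p.max() >= arr.size):
        raise ValueError("wavelet position outside transform length")
    values = arr[v_p] if v_p.size else np.zeros(0)
    sparse = np.zeros_like(arr)
    sparse[v_p] = arr[v_p]
    coeffs = pywt.array_to_coeffs(sparse, slices, output_format="wavedec")
    recon = pywt.waverec(coeffs, w, mode="periodization")[:n]
    x = _pad_pow2(np.asarray(diff_window, dtype=float))[:n]
    err = float(np.sqrt(np.sum((recon - x) ** 2)))
    extra = np.zeros(0, dtype=int)
    if err > l2_tolerance:
        cand = np.where(np.abs(arr) > thr)[0]
        extra = np.setdiff1d(cand, v_p)
    return WaveletFeatureResult(values=values, l2_error=err,
                                extra_positions=extra)


# ------------------------------------------------------- dictionary

@dataclass
class FeatureDictionary:
    """Named dictionary of informed and agnostic entry definitions.

    ``wavelet_positions_`` is learned from training data via
    ``fit_wavelets`` (trailing underscore: fitted state).
    """

    use_calcium: bool = True
    use_k_markers: bool = True
    use_wavelets: bool = True
    wavelet: str = "db4"
    wavelet_threshold: float = 50.0     # uV; above the DWT noise floor of
                                        # |drug-ctrl| windows at 10 uV FP noise
    wavelet_level: int | None = None
    l2_tolerance: float = np.inf
    n_resample: int = 256               # K-marker / wavelet window length
    x_percent: float = 90.0             # CDX percentage
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    wavelet_positions_: np.ndarray | None = None

    def entry_names(self) -> list[str]:
        names = [f"{m}_ratio" for m in FP_MARKERS]
        if self.use_calcium:
            names += [f"{m}_ratio" for m in CA_MARKERS]
        if self.use_k_markers:
            names += list(K_MARKERS)
        if self.use_wavelets and self.wavelet_positions_ is not None:
            names += [f"wv_{p}" for p in self.wavelet_positions_]
        return names

    def entry_tags(self) -> dict:
        """informed/agnostic tag per entry name."""
        tags = {}
        for name in self.entry_names():
            tags[name] = "agnostic" if name.startswith("wv_") else "informed"
        return tags

    def to_file(self, path) -> None:
        """Write the dictionary definition (entries, tags, parameters)."""
        import json
        from pathlib import Path
        spec = {
            "entries": [{"name": n, "tag": t}
                        for n, t in self.entry_tags().items()],
            "params": {
                "use_calcium": self.use_calcium,
                "use_k_markers": self.use_k_markers,
                "use_wavelets": self.use_wavelets,
                "wavelet": self.wavelet,
                "wavelet_threshold": self.wavelet_threshold,
                "wavelet_level": self.wavelet_level,
                "l2_tolerance": (None if np.isinf(self.l2_tolerance)
                                 else self.l2_tolerance),
                "n_resample": self.n_resample,
                "x_percent": self.x_percent,
            },
            "wavelet_positions": (None if self.wavelet_positions_ is None
                                  else self.wavelet_positions_.tolist()),
        }
        Path(path).write_text(json.dumps(spec, indent=1))

    @classmethod
    def from_file(cls, path) -> "FeatureDictionary":
        import json
        from pathlib import Path
        spec = json.loads(Path(path).read_text())
        params = dict(spec["params"])
        if params.get("l2_tolerance") is None:
            params["l2_tolerance"] = np.inf
        d = cls(**params)
        if spec.get("wavelet_positions") is not None:
            d.wavelet_positions_ = np.asarray(spec["wavelet_positions"],
                                              dtype=int)
        return d

    def fit_wavelets(self, pairs) -> "FeatureDictionary":
        """Learn wavelet positions from training (control, drug) pairs."""
        if not self.use_wavelets:
            return self
        diffs = []
        for ctrl, drug in pairs:
            try:
                diffs.append(self._diff_window(ctrl, drug))
            except QuiescentSignalError:
                continue
        if not diffs:
            raise ValueError("no usable training pairs for wavelet selection")
        self.wavelet_positions_ = wavelet_positions(
            diffs, self.wavelet_threshold, self.wavelet, self.wavelet_level)
        return self

    # -- helpers ---------------------------------------------------------

    def _gold_electrode(self, rec) -> int:
        """Electrode with the largest control repolarization amplitude."""
        best, best_ra = 0, -np.inf
        for k, sig in enumerate(rec.fp_traces):
            try:
                ra = fp_biomarkers(sig, self.segment).ra
            except QuiescentSignalError:
                continue
            if ra > best_ra:
                best, best_ra = k, ra
        if not np.isfinite(best_ra):
            raise QuiescentSignalError("all electrodes quiescent")
        return best

    def _repol_window(self, sig: TimeSignal) -> np.ndarray:
        _, _, repol = segment_fp(sig, self.segment)
        return _resample_window(sig, repol, self.n_resample)

    def _diff_window(self, ctrl, drug) -> np.ndarray:
        """|drug - control| over the plateau + repolarization phases."""
        k = self._gold_electrode(ctrl)
        sc, sd = ctrl.fp_traces[k], drug.fp_traces[k]
        _, plateau_c, repol_c = segment_fp(sc, self.segment)
        _, plateau_d, repol_d = segment_fp(sd, self.segment)
        wc = Window(plateau_c.start, repol_c.end)
        wd = Window(plateau_d.start, repol_d.end)
        c = _resample_window(sc, wc, self.n_resample)
        d = _resample_window(sd, wd, self.n_resample)
        return np.abs(d - c)

    def sample_features(self, ctrl, drug) -> dict:
        """Dictionary entries for one paired (control, drug) sample.

        FP marker ratios use the per-electrode ratio median across the
        well; K markers and wavelets use the gold electrode.
        """
        ratios = []
        for sc, sd in zip(ctrl.fp_traces, drug.fp_traces):
            try:
                bc = fp_biomarkers(sc, self.segment).as_dict()
                bd = fp_biomarkers(sd, self.segment).as_dict()
            except QuiescentSignalError:
                continue
            ratios.append(ratio_to_control(bd, bc))
        if not ratios:
            raise QuiescentSignalError("no scorable electrode in the well")
        feats = {f"{m}_ratio": float(np.nanmedian([r[m] for r in ratios]))
                 for m in FP_MARKERS}

        if self.use_calcium:
            if ctrl.calcium is not None and drug.calcium is not None:
                bc = calcium_biomarkers(ctrl.calcium, self.x_percent).as_dict()
                bd = calcium_biomarkers(drug.calcium, self.x_percent).as_dict()
                feats.update({f"{m}_ratio": v for m, v in
                              ratio_to_control(bd, bc).items()})
            else:
                feats.update({f"{m}_ratio": float("nan") for m in CA_MARKERS})

        if self.use_k_markers:
            k = self._gold_electrode(ctrl)
            wc = self._repol_window(ctrl.fp_traces[k])
            wd = self._repol_window(drug.fp_traces[k])
            _, _, repol_d = segment_fp(drug.fp_traces[k], self.segment)
            step = repol_d.span / (self.n_resample - 1)
            km = repolarization_markers(wd, wc, n_points=None, dt=step)
            feats.update(km.as_dict())

        if self.use_wavelets and self.wavelet_positions_ is not None:
            diff = self._diff_window(ctrl, drug)
            res = wavelet_features(diff, self.wavelet_positions_,
                                   self.wavelet_threshold,
                                   self.l2_tolerance, self.wavelet,
                                   self.wavelet_level)
            if res.needs_refresh:
                logger.warning("wavelet dictionary refresh suggested: "
                               "positions %s", res.extra_positions)
            feats.update({f"wv_{p}": float(val) for p, val in
                          zip(self.wavelet_positions_, res.values)})
        return feats


# --------------------------------------------------------- feature matrix

@dataclass
class FeatureMatrix:
    """Sample x dictionary-entry matrix with provenance and labels."""

    values: pd.DataFrame           # rows: samples, columns: entries
    provenance: pd.DataFrame       # sample_id, compound, concentration, ...
    labels: dict = field(default_factory=dict)   # task name -> label Series
    tags: dict = field(default_factory=dict)     # entry -> informed/agnostic

    @property
    def n_samples(self) -> int:
        return len(self.values)

    @property
    def entry_names(self) -> list[str]:
        return list(self.values.columns)

    def to_files(self, stem) -> None:
        """values to <stem>.csv, provenance/labels/tags to <stem>.meta.json."""
        from pathlib import Path
        stem = Path(stem)
        self.values.to_csv(stem.with_suffix(".csv"), index=False)
        meta = {
            "provenance": self.provenance.to_dict(orient="list"),
            "labels": {k: list(v) for k, v in self.labels.items()},
            "tags": self.tags,
        }
        import json
        stem.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_files(cls, stem) -> "FeatureMatrix":
        from pathlib import Path
        import json
        stem = Path(stem)
        values = pd.read_csv(stem.with_suffix(".csv"))
        meta = json.loads(stem.with_suffix(".meta.json").read_text())
        return cls(values=values,
                   provenance=pd.DataFrame(meta["provenance"]),
                   labels={k: pd.Series(v) for k, v in meta["labels"].items()},
                   tags=meta["tags"])


def build_feature_matrix(pairs, dictionary: FeatureDictionary,
                         train_mask=None) -> FeatureMatrix:
    """Assemble the dictionary matrix F_s from paired recordings.

    ``pairs`` is a sequence of (control, drug) MEARecording pairs; one
    row per pair, in input order. Quiescent samples are dropped with a
    logged reason. Undefined ratios (NaN) are imputed with the column
    median computed over ``train_mask`` rows (all surviving rows when
    None) and the imputation is recorded in the provenance.
    """
    rows, prov, kept = [], [], []
    for i, (ctrl, drug) in enumerate(pairs):
        try:
            feats = dictionary.sample_features(ctrl, drug)
        except QuiescentSignalError as exc:
            logger.info("sample %d (%s) dropped: %s", i, drug.well_id, exc)
            continue
        rows.append(feats)
        kept.append(i)
        prov.append({
            "sample_id": i, "well_id": drug.well_id,
            "compound": drug.compound, "concentration": drug.concentration,
            "seed": drug.seed, "in_silico": True,
        })
    if not rows:
        raise ValueError("all samples dropped (quiescent or noisy)")
    values = pd.DataFrame(rows, columns=dictionary.entry_names())
    prov = pd.DataFrame(prov)

    if train_mask is None:
        fit_rows = np.ones(len(values), dtype=bool)
    else:
        train_mask = np.asarray(train_mask)
        fit_rows = train_mask[np.array(kept)]
    imputed = {}
    for col in values.columns:
        if values[col].isna().any():
            med = float(values.loc[fit_rows, col].median())
            if np.isnan(med):
                med = 0.0
            imputed[col] = med
            values[col] = values[col].fillna(med)
    prov.attrs["imputed"] = imputed
    return FeatureMatrix(values=values, provenance=prov,
                         tags=dictionary.entry_tags())
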