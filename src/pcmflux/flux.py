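"""Single-molecule binding/unbinding flux analysis.

Measures where single labeled molecules bind to and leave a centrosome
relative to its mother centriole. The chain is: LoG spot detection in the
single-molecule channel, frame-to-frame linking with one-frame gap closing
(blink tolerance), selection of clean binding events by the five rules
(sparse labeling; observed entry and exit; more than one time point at the
centrosome; one-frame blink tolerance; no simultaneous events at one
centrosome), and the paired In/Out distance statistic: the centriole-to-
molecule distance at the first and the last colocalized time point. A mean
Out distance exceeding the mean In distance is the signature of outward
molecular flux through the pericentriolar material; equality is what a
static-binding (turnover-gradient) regime produces.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.optimize import linear_sum_assignment

__all__ = [
    "Spot",
    "Track",
    "LinkParams",
    "BindingEvent",
    "FluxSummary",
    "detect_spots_log",
    "link_tracks",
    "check_sparse_labeling",
    "select_binding_events",
    "event_distances",
    "flux_statistic",
    "analyze_flux_movie",
]

_BIG = 1e18


@dataclass
class Spot:
    """A subpixel spot detection in one frame."""

    frame: int
    y: float
    x: float
    quality: float
    brightest_pixel: tuple[int, int] | None = None


@dataclass
class Track:
    """An ordered sequence of linked spots (strictly increasing frames)."""

    id: int
    spots: list[Spot] = field(default_factory=list)

    @property
    def frames(self) -> list[int]:
        return [s.frame for s in self.spots]


@dataclass(frozen=True)
class LinkParams:
    """LAP-tracker caps: link distance, gap-close distance, max frame gap."""

    max_link_um: float = 2.0
    max_gap_um: float = 2.0
    max_frame_gap: int = 1

    def __post_init__(self) -> None:
        if self.max_link_um <= 0 or self.max_gap_um <= 0 or self.max_frame_gap < 0:
            raise ValueError("linking caps must be positive")


@dataclass
class BindingEvent:
    """One candidate single-molecule visit to a centrosome."""

    track_id: int
    centrosome_id: int
    t_in: int
    t_out: int
    duration_s: float
    rejection_code: str  # accepted | rule_ii | rule_iii | rule_v | off_centrosome
    d_in_nm: float | None = None
    d_out_nm: float | None = None
    spot_in: Spot | None = None
    spot_out: Spot | None = None


@dataclass
class FluxSummary:
    """Paired In/Out distance descriptives and test for a set of events."""

    n_events: int
    d_in_mean_nm: float
    d_in_sd_nm: float
    d_in_median_nm: float
    d_in_quartiles_nm: tuple[float, float]
    d_out_mean_nm: float
    d_out_sd_nm: float
    d_out_median_nm: float
    d_out_quartiles_nm: tuple[float, float]
    diff_mean_nm: float
    diff_ci95_nm: tuple[float, float]
    p_value: float


def detect_spots_log(
    image: np.ndarray,
    pixel_size_nm: float,
    estimated_diameter_um: float = 0.5,
    quality_threshold: float | None = None,
    frame: int = 0,
) -> list[Spot]:
    """Scale-normalized Laplacian-of-Gaussian spot detection with subpixel refinement.

    The filter scale is sigma = diameter / (2 sqrt 2). Local maxima of the
    (sign-flipped, scale-normalized) LoG response above ``quality_threshold``
    become spots; if the threshold is None it is set automatically to 10
    robust standard deviations of the response. Subpixel positions come from
    a quadratic fit to the 3x3 response neighborhood; the brightest raw
    pixel within one radius is recorded alongside.
    """
    image = np.asarray(image, dtype=float)
    d_px = estimated_diameter_um * 1000.0 / pixel_size_nm
    if d_px < 3:
        raise ValueError("estimated diameter must be at least 3 px at this pixel size")
    sigma = d_px / (2.0 * math.sqrt(2.0))
    resp = -(sigma**2) * ndimage.gaussian_laplace(image, sigma, mode="nearest")
    if quality_threshold is None:
        med = np.median(resp)
        mad = np.median(np.abs(resp - med)) + 1e-12
        quality_threshold = med + 10.0 * 1.4826 * mad
    footprint = int(max(3, 2 * round(sigma) + 1))
    dil = ndimage.maximum_filter(resp, size=footprint, mode="nearest")
    peaks = np.argwhere((resp == dil) & (resp > quality_threshold))
    ny, nx = image.shape
    r_int = max(1, int(round(d_px / 2.0)))
    spots: list[Spot] = []
    for py, px in peaks:
        if py < 1 or py > ny - 2 or px < 1 or px > nx - 2:
            continue
        n3 = resp[py - 1 : py + 2, px - 1 : px + 2]
        gy = (n3[2, 1] - n3[0, 1]) / 2.0
        gx = (n3[1, 2] - n3[1, 0]) / 2.0
        hyy = n3[2, 1] - 2.0 * n3[1, 1] + n3[0, 1]
        hxx = n3[1, 2] - 2.0 * n3[1, 1] + n3[1, 0]
        hxy = (n3[2, 2] - n3[2, 0] - n3[0, 2] + n3[0, 0]) / 4.0
        det = hyy * hxx - hxy * hxy
        if det > 0 and hyy < 0:
            dy = -(hxx * gy - hxy * gx) / det
            dx = -(hyy * gx - hxy * gy) / det
        else:
            dy = dx = 0.0
        dy = float(np.clip(dy, -1.0, 1.0))
        dx = float(np.clip(dx, -1.0, 1.0))
        y0 = max(0, py - r_int)
        y1 = min(ny, py + r_int + 1)
        x0 = max(0, px - r_int)
        x1 = min(nx, px + r_int + 1)
        sub = image[y0:y1, x0:x1]
        by, bx = np.unravel_index(np.argmax(sub), sub.shape)
        spots.append(
            Spot(
                frame=frame,
                y=py + dy,
                x=px + dx,
                quality=float(resp[py, px]),
                brightest_pixel=(y0 + int(by), x0 + int(bx)),
            )
        )
    return spots


def _match_frames(
    a: np.ndarray, b: np.ndarray, cap_px: float
) -> list[tuple[int, int]]:
    """Min-total-squared-distance bipartite matching with a per-pair cap.

    Implemented as a padded linear assignment where leaving a spot unmatched
    costs cap^2, so a pair is linked iff its squared distance is below the
    cap and the global total cost is minimal.
    """
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        return []
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    cap2 = cap_px**2
    cost = np.full((n1 + n2, n2 + n1), 0.0)
    top_left = np.where(d2 <= cap2, d2, _BIG)
    cost[:n1, :n2] = top_left
    cost[:n1, n2:] = _BIG
    cost[:n1, n2:][np.arange(n1), np.arange(n1)] = cap2
    cost[n1:, :n2] = _BIG
    cost[n1:, :n2][np.arange(n2), np.arange(n2)] = cap2
    rows, cols = linear_sum_assignment(cost)
    out = []
    for r, c in zip(rows, cols):
        if r < n1 and c < n2 and d2[r, c] <= cap2:
            out.append((int(r), int(c)))
    return out


def link_tracks(
    spots: list[Spot],
    params: LinkParams = LinkParams(),
    pixel_size_nm: float = 100.0,
) -> list[Track]:
    """Link per-frame spots into tracks (LAP-style), then close one-frame gaps.

    Frame-to-frame assignment minimizes total squared distance with a hard
    per-pair cap of ``max_link_um``; unmatched spots terminate or start
    tracks. Track ends are then joined to track starts up to
    ``max_frame_gap`` missing frames later, within ``max_gap_um``, again by
    minimum-cost matching. Every spot belongs to exactly one track.
    """
    by_frame: dict[int, list[Spot]] = defaultdict(list)
    for s in spots:
        by_frame[s.frame].append(s)
    if not by_frame:
        return []
    frames = sorted(by_frame)
    cap_link_px = params.max_link_um * 1000.0 / pixel_size_nm

    tracks: list[Track] = []
    open_by_spot: dict[int, Track] = {}  # id(spot of track tail) -> track
    prev_frame = None
    for f in frames:
        cur = by_frame[f]
        if prev_frame is not None and f == prev_frame + 1:
            prev = by_frame[prev_frame]
            a = np.array([[s.y, s.x] for s in prev])
            b = np.array([[s.y, s.x] for s in cur])
            matches = _match_frames(a, b, cap_link_px)
        else:
            matches = []
        matched_cur = set()
        for i, j in matches:
            tr = open_by_spot.pop(id(by_frame[prev_frame][i]))
            tr.spots.append(cur[j])
            open_by_spot[id(cur[j])] = tr
            matched_cur.add(j)
        for j, s in enumerate(cur):
            if j not in matched_cur:
                tr = Track(id=len(tracks), spots=[s])
                tracks.append(tr)
                open_by_spot[id(s)] = tr
        prev_frame = f

    if params.max_frame_gap >= 1:
        tracks = _close_gaps(tracks, params, pixel_size_nm)
    tracks = [t for t in tracks if t.spots]
    for i, t in enumerate(tracks):
        t.id = i
    return tracks


def _close_gaps(tracks: list[Track], params: LinkParams, pixel_size_nm: float) -> list[Track]:
    cap_px = params.max_gap_um * 1000.0 / pixel_size_nm
    ends = [(t, t.spots[-1]) for t in tracks]
    starts = [(t, t.spots[0]) for t in tracks]
    n_e, n_s = len(ends), len(starts)
    if n_e == 0 or n_s == 0:
        return tracks
    cost = np.full((n_e + n_s, n_s + n_e), _BIG)
    cap2 = cap_px**2
    for i, (te, se) in enumerate(ends):
        for j, (ts, ss) in enumerate(starts):
            if te is ts:
                continue
            gap = ss.frame - se.frame - 1
            if 1 <= gap <= params.max_frame_gap:
                d2 = (se.y - ss.y) ** 2 + (se.x - ss.x) ** 2
                if d2 <= cap2:
                    cost[i, j] = d2
    cost[:n_e, n_s:][np.arange(n_e), np.arange(n_e)] = cap2
    cost[n_e:, :n_s][np.arange(n_s), np.arange(n_s)] = cap2
    cost[n_e:, n_s:] = 0.0
    rows, cols = linear_sum_assignment(cost)
    joins = [
        (i, j)
        for i, j in zip(rows, cols)
        if i < n_e and j < n_s and cost[i, j] < cap2
    ]
    # merge chains in increasing time order
    joins.sort(key=lambda ij: ends[ij[0]][1].frame)
    owner = {id(t): t for t in tracks}
    merged_away: set[int] = set()
    for i, j in joins:
        te = ends[i][0]
        ts = starts[j][0]
        # walk to the surviving upstream track if te was itself merged
        while id(te) in merged_away:
            te = owner[id(te)]
        if te is ts:
            continue
        te.spots.extend(ts.spots)
        owner[id(ts)] = te
        merged_away.add(id(ts))
        ts.spots = []
    return [t for t in tracks if id(t) not in merged_away]


def check_sparse_labeling(
    labeled_fraction_per_frame, threshold: float = 0.05
) -> tuple[bool, float]:
    """Sparse-labeling gate: pass iff the labeled-centrosome fraction stays
    strictly below ``threshold`` at every time point."""
    frac = np.asarray(labeled_fraction_per_frame, dtype=float)
    if frac.size == 0 or np.any(~np.isfinite(frac)):
        raise ValueError("labeled fractions undefined (no centrosomes?)")
    max_frac = float(frac.max())
    return bool(np.all(frac < threshold)), max_frac


def _centriole_arrays(centriole_tracks) -> dict[int, dict[int, np.ndarray]]:
    """Normalize centriole tracks to {centrosome_id: {frame: (y, x)}}."""
    if isinstance(centriole_tracks, pd.DataFrame):
        out: dict[int, dict[int, np.ndarray]] = {}
        for row in centriole_tracks.itertuples():
            out.setdefault(int(row.centrosome_id), {})[int(row.frame)] = np.array(
                [row.y_px, row.x_px]
            )
        return out
    return centriole_tracks


def select_binding_events(
    tracks: list[Track],
    centriole_tracks,
    assoc_radius_um: float = 1.5,
    pixel_size_nm: float = 100.0,
    n_frames: int | None = None,
    frame_interval_s: float = 10.0,
) -> list[BindingEvent]:
    """Apply the binding-event selection rules to linked molecule tracks.

    A *visit* is a maximal run of track points within ``assoc_radius_um`` of
    one centriole, tolerating single-frame interruptions (the blink rule is
    already embodied in gap-closed tracks). Rejections: a visit abutting the
    movie's first or last frame has no observed entry or exit (rule ii); a
    visit observed at the centrosome for a single time point (rule iii);
    visits at one centrosome overlapping another visit in time (rule v).
    Tracks never near any centriole yield one ``off_centrosome`` record.
    Sparse labeling (rule i) is a movie-level gate checked separately via
    :func:`check_sparse_labeling`.
    """
    cents = _centriole_arrays(centriole_tracks)
    if not cents:
        raise ValueError("no centriole tracks supplied")
    if n_frames is None:
        n_frames = 1 + max(s.frame for t in tracks for s in t.spots) if tracks else 0
    radius_px = assoc_radius_um * 1000.0 / pixel_size_nm

    events: list[BindingEvent] = []
    visits_by_cid: dict[int, list[BindingEvent]] = defaultdict(list)
    for tr in sorted(tracks, key=lambda t: t.id):
        assoc: list[tuple[Spot, int | None]] = []
        for s in tr.spots:
            best_cid, best_d = None, None
            for cid, per_frame in cents.items():
                pos = per_frame.get(s.frame)
                if pos is None:
                    continue
                d = math.hypot(s.y - pos[0], s.x - pos[1])
                if d <= radius_px and (best_d is None or d < best_d):
                    best_cid, best_d = cid, d
            assoc.append((s, best_cid))
        # maximal runs per centriole, tolerating 1-frame interruptions
        visits: list[tuple[int, list[Spot]]] = []
        for s, cid in assoc:
            if cid is None:
                continue
            if visits and visits[-1][0] == cid and s.frame - visits[-1][1][-1].frame <= 2:
                visits[-1][1].append(s)
            else:
                visits.append((cid, [s]))
        if not visits:
            events.append(
                BindingEvent(
                    track_id=tr.id,
                    centrosome_id=-1,
                    t_in=tr.spots[0].frame,
                    t_out=tr.spots[-1].frame,
                    duration_s=0.0,
                    rejection_code="off_centrosome",
                )
            )
            continue
        for cid, run in visits:
            t_in, t_out = run[0].frame, run[-1].frame
            if t_in <= 0 or t_out >= n_frames - 1:
                code = "rule_ii"  # entry or exit not observed
            elif len(run) == 1:
                code = "rule_iii"  # single time point at the centrosome
            else:
                code = "accepted"
            ev = BindingEvent(
                track_id=tr.id,
                centrosome_id=cid,
                t_in=t_in,
                t_out=t_out,
                duration_s=(t_out - t_in) * frame_interval_s,
                rejection_code=code,
                spot_in=run[0],
                spot_out=run[-1],
            )
            events.append(ev)
            visits_by_cid[cid].append(ev)

    # rule v: simultaneous events at the same centrosome
    for cid, evs in visits_by_cid.items():
        for i, a in enumerate(evs):
            for b in evs[i + 1 :]:
                if a.t_in <= b.t_out and b.t_in <= a.t_out:
                    for ev in (a, b):
                        if ev.rejection_code == "accepted":
                            ev.rejection_code = "rule_v"
    return events


def _centriole_com(
    image: np.ndarray, center: np.ndarray, box_px: int
) -> np.ndarray:
    """Intensity-weighted center of mass of the Otsu-segmented centriole region."""
    from .quant import otsu_threshold

    ny, nx = image.shape
    cy, cx = int(round(center[0])), int(round(center[1]))
    h = box_px // 2
    y0, y1 = max(0, cy - h), min(ny, cy + h + 1)
    x0, x1 = max(0, cx - h), min(nx, cx + h + 1)
    crop = image[y0:y1, x0:x1]
    try:
        thr = otsu_threshold(crop)
    except ValueError:
        return center.astype(float)
    mask = crop > thr
    if not mask.any():
        return center.astype(float)
    w = np.where(mask, crop, 0.0)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    m = w.sum()
    return np.array([(w * yy).sum() / m, (w * xx).sum() / m])


def event_distances(
    event: BindingEvent,
    centriole_tracks,
    pixel_size_nm: float,
    mode: str = "brightest_pixel",
    green_stack: np.ndarray | None = None,
    com_box_um: float = 1.0,
) -> tuple[float, float] | None:
    """Centriole-to-molecule distances (nm) at the first and last colocalized frame.

    The centriole reference is the intensity-weighted center of mass of its
    Otsu-segmented region in the green channel (within a ``com_box_um`` box
    around the tracked position) when a green stack is supplied, else the
    tracked centriole position. The molecule position is its brightest raw
    pixel (``mode='brightest_pixel'``, the default) or the subpixel centroid
    (``mode='subpixel'``). Returns None (event flagged dropped) if the
    centriole is missing at both endpoints even with a one-frame fallback.
    """
    if mode not in ("brightest_pixel", "subpixel"):
        raise ValueError("mode must be 'brightest_pixel' or 'subpixel'")
    cents = _centriole_arrays(centriole_tracks)
    per_frame = cents.get(event.centrosome_id)
    if per_frame is None:
        return None
    box_px = max(3, int(round(com_box_um * 1000.0 / pixel_size_nm)))

    def centriole_ref(frame: int) -> np.ndarray | None:
        for f in (frame, frame - 1, frame + 1):
            pos = per_frame.get(f)
            if pos is not None:
                if green_stack is not None:
                    return _centriole_com(np.asarray(green_stack[f], dtype=float), pos, box_px)
                return np.asarray(pos, dtype=float)
        return None

    def molecule_pos(spot: Spot) -> np.ndarray:
        if mode == "brightest_pixel" and spot.brightest_pixel is not None:
            return np.array(spot.brightest_pixel, dtype=float)
        return np.array([spot.y, spot.x])

    out = []
    for spot, frame in ((event.spot_in, event.t_in), (event.spot_out, event.t_out)):
        ref = centriole_ref(frame)
        if ref is None or spot is None:
            return None
        mol = molecule_pos(spot)
        out.append(float(np.hypot(*(mol - ref)) * pixel_size_nm))
    event.d_in_nm, event.d_out_nm = out
    return out[0], out[1]


def flux_statistic(events: list[BindingEvent]) -> FluxSummary:
    """Paired In/Out descriptives and Wilcoxon signed-rank test over accepted events."""
    acc = [e for e in events if e.rejection_code == "accepted" and e.d_in_nm is not None]
    if not acc:
        raise ValueError("no accepted events with distances")
    d_in = np.array([e.d_in_nm for e in acc])
    d_out = np.array([e.d_out_nm for e in acc])
    diff = d_out - d_in
    n = len(acc)
    if n >= 5 and np.any(diff != 0):
        p = float(stats.wilcoxon(diff).pvalue)
    else:
        p = 1.0
    if n > 1:
        se = diff.std(ddof=1) / math.sqrt(n)
        tcrit = stats.t.ppf(0.975, n - 1)
        ci = (float(diff.mean() - tcrit * se), float(diff.mean() + tcrit * se))
    else:
        ci = (float("nan"), float("nan"))
    q = lambda v: (float(np.percentile(v, 25)), float(np.percentile(v, 75)))
    return FluxSummary(
        n_events=n,
        d_in_mean_nm=float(d_in.mean()),
        d_in_sd_nm=float(d_in.std(ddof=1)) if n > 1 else 0.0,
        d_in_median_nm=float(np.median(d_in)),
        d_in_quartiles_nm=q(d_in),
        d_out_mean_nm=float(d_out.mean()),
        d_out_sd_nm=float(d_out.std(ddof=1)) if n > 1 else 0.0,
        d_out_median_nm=float(np.median(d_out)),
        d_out_quartiles_nm=q(d_out),
        diff_mean_nm=float(diff.mean()),
        diff_ci95_nm=ci,
        p_value=p,
    )


def analyze_flux_movie(
    stack: np.ndarray,
    pixel_size_nm: float,
    frame_interval_s: float,
    mol_diameter_um: float = 0.5,
    link_params: LinkParams = LinkParams(),
    assoc_radius_um: float = 1.5,
    mode: str = "brightest_pixel",
    centriole_diameter_um: float = 0.5,
) -> tuple[list[Track], list[BindingEvent], FluxSummary | None]:
    """End-to-end flux analysis of a two-channel (centriole, molecule) movie.

    Centrioles are detected on the time-averaged centriole channel (they are
    persistent) and treated as static reference tracks; molecules are
    LoG-detected per frame, linked with gap closing, filtered by the
    selection rules, and measured. Returns (tracks, events, summary);
    summary is None when no event survives selection.
    """
    n_frames = stack.shape[0]
    green_mean = stack[:, 0].mean(axis=0)
    cent_spots = detect_spots_log(green_mean, pixel_size_nm, centriole_diameter_um)
    cent_tracks = {
        cid: {f: np.array([s.y, s.x]) for f in range(n_frames)}
        for cid, s in enumerate(cent_spots)
    }
    mol_spots: list[Spot] = []
    for f in range(n_frames):
        mol_spots.extend(
            detect_spots_log(stack[f, 1], pixel_size_nm, mol_diameter_um, frame=f)
        )
    tracks = link_tracks(mol_spots, link_params, pixel_size_nm)
    events = select_binding_events(
        tracks,
        cent_tracks,
        assoc_radius_um,
        pixel_size_nm,
        n_frames=n_frames,
        frame_interval_s=frame_interval_s,
    )
    for ev in events:
        if ev.rejection_code == "accepted":
            got = event_distances(
                ev, cent_tracks, pixel_size_nm, mode=mode, green_stack=stack[:, 0]
            )
            if got is None:
                ev.rejection_code = "no_centriole"
    accepted = [e for e in events if e.rejection_code == "accepted"]
    summary = flux_statistic(accepted) if accepted else None
    return tracks, events, summary
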