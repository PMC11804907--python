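"""Hand-enumerated fixtures for the binding-event selection rules.

``selection_rule_fixture`` builds ten toy molecule tracks around two static
centrioles, one per selection-rule outcome, together with the hand-derived
expected rejection code for each track. It is the frozen truth table for
the event-selection logic: every rule is exercised at least once, including
the one-frame blink tolerance and visits abutting the movie boundary.

Geometry: 100 nm pixels, association radius 1.5 um (15 px), movie of 20
frames, centriole A at (32, 32), centriole B at (32, 96). "Near" positions
sit 5 px (500 nm) from a centriole; "far" positions are > 25 px away.
"""

from __future__ import annotations

import numpy as np

from .flux import Spot, Track

N_FRAMES = 20
PIXEL_SIZE_NM = 100.0
ASSOC_RADIUS_UM = 1.5
CENT_A = (32.0, 32.0)
CENT_B = (32.0, 96.0)

# per track: list of (frame, y, x); "far" points are offset well outside the
# association radius but within linking range of each other
_NEAR_A = (37.0, 32.0)
_NEAR_B = (37.0, 96.0)
_FAR_A = (54.0, 32.0)  # 22 px from A, one 1.7 um hop from _NEAR_A
_FAR_B = (54.0, 96.0)

_TRACKS: dict[int, list[tuple[int, float, float]]] = {
    # 0: clean visit with observed entry and exit -> accepted
    0: [(2, *_FAR_A), (3, *_FAR_A), (4, *_NEAR_A), (5, *_NEAR_A), (6, *_NEAR_A),
        (7, *_NEAR_A), (8, *_NEAR_A), (9, *_FAR_A), (10, *_FAR_A)],
    # 1: at the centrosome for exactly one time point -> rule_iii
    1: [(14, *_FAR_A), (15, *_NEAR_A), (16, *_FAR_A)],
    # 2: already colocalized at the movie's first frame (entry unobserved) -> rule_ii
    2: [(0, *_NEAR_A), (1, *_NEAR_A), (2, *_NEAR_A), (3, *_FAR_A), (4, *_FAR_A)],
    # 3: still colocalized at the movie's last frame (exit unobserved) -> rule_ii
    3: [(15, *_FAR_A), (16, 37.0, 33.0), (17, 37.0, 33.0), (18, 37.0, 33.0),
        (19, 37.0, 33.0)],
    # 4 & 5: two simultaneous visits at centriole A -> both rule_v
    4: [(9, *_FAR_A), (10, 32.0, 37.0), (11, 32.0, 37.0), (12, 32.0, 37.0),
        (13, 32.0, 37.0), (14, *_FAR_A)],
    5: [(11, 12.0, 36.0), (12, 27.0, 32.0), (13, 27.0, 32.0), (14, 27.0, 32.0),
        (15, 12.0, 36.0)],
    # 6: never near any centriole -> off_centrosome
    6: [(3, 100.0, 60.0), (4, 100.0, 60.0), (5, 100.0, 61.0)],
    # 7: one-frame blink inside a visit at B (frame 10 missing) -> accepted as one visit
    7: [(7, *_FAR_B), (8, *_NEAR_B), (9, *_NEAR_B), (11, *_NEAR_B),
        (12, *_NEAR_B), (13, *_FAR_B)],
    # 8: appears mid-movie already bound (absent before: appearance = binding) -> accepted
    8: [(15, *_NEAR_B), (16, *_NEAR_B), (17, *_NEAR_B), (18, *_FAR_B)],
    # 9: valid visit at B overlapping track 0's visit at A in time
    #    (different centrosome, so NOT rule v) -> accepted
    9: [(3, 10.0, 96.0), (4, 27.0, 96.0), (5, 27.0, 96.0), (6, 27.0, 96.0),
        (7, 10.0, 96.0)],
}

EXPECTED_CODES: dict[int, str] = {
    0: "accepted",
    1: "rule_iii",
    2: "rule_ii",
    3: "rule_ii",
    4: "rule_v",
    5: "rule_v",
    6: "off_centrosome",
    7: "accepted",
    8: "accepted",
    9: "accepted",
}

# sparse-labeling (rule i) fixtures: per-frame labeled-centrosome fractions
SPARSE_PASS = np.full(N_FRAMES, 0.02)
SPARSE_FAIL_SPIKE = np.array([0.02] * 10 + [0.06] + [0.02] * 9)
SPARSE_FAIL_BOUNDARY = np.array([0.02] * 19 + [0.05])  # exactly 5%: strict < fails


def selection_rule_fixture() -> tuple[list[Track], dict[int, dict[int, np.ndarray]], dict[int, str]]:
    """Build the ten-track fixture: (tracks, centriole tracks, expected codes)."""
    tracks = []
    for tid, pts in _TRACKS.items():
        spots = [Spot(frame=f, y=y, x=x, quality=10.0) for f, y, x in pts]
        tracks.append(Track(id=tid, spots=spots))
    cents = {
        0: {f: np.array(CENT_A) for f in range(N_FRAMES)},
        1: {f: np.array(CENT_B) for f in range(N_FRAMES)},
    }
    return tracks, cents, dict(EXPECTED_CODES)
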