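"""Cross-frame particle linking so each physical particle is counted once.

A particle drifting through the detection window is seen on many
consecutive frames; naive per-frame counting would overcount it badly.
Candidates are linked frame to frame by gated greedy nearest-neighbour
matching against the flow-predicted position (previous centroid displaced
by the expected per-frame flow).  The gates — maximum link distance,
maximum lateral displacement, and bounded frame-to-frame size ratio —
mirror the de-duplication parameters of the original interface (distance
between objects, vertical/horizontal movement range, and their ratios).

A track is counted exactly once, when it terminates (exits the window or
the video ends); its representative candidate — the largest-area member,
i.e. the most in-focus, most fully stained view — supplies every reported
measurement and the crop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detect import DetectionWindow, ParticleCandidate

__all__ = ["LinkParams", "Track", "link_frames", "count_events", "Tracker"]


@dataclass
class LinkParams:
    max_link_distance_px: float = 12.0
    expected_flow_dx_px: float = 8.0   # signed, along the flow axis (+x)
    max_lateral_dy_px: float = 10.0
    max_ratio_change: float = 2.0      # feret_max ratio gate, symmetric
    max_gap_frames: int = 2

    def __post_init__(self) -> None:
        if self.max_link_distance_px <= 0 or self.max_lateral_dy_px <= 0:
            raise ValueError("link gates must be positive")
        if self.max_ratio_change < 1.0:
            raise ValueError("max_ratio_change is interpreted symmetrically, >= 1")
        if self.max_gap_frames < 0:
            raise ValueError("max_gap_frames must be >= 0")


@dataclass
class Track:
    track_id: int
    candidates: list[ParticleCandidate] = field(default_factory=list)
    missed: int = 0                     # consecutive frames without a match
    counted: bool = False

    @property
    def representative(self) -> ParticleCandidate:
        """Largest-area member; earliest frame wins ties."""
        return max(self.candidates, key=lambda c: (c.area_px, -c.frame_index))

    @property
    def last(self) -> ParticleCandidate:
        return self.candidates[-1]

    @property
    def first_frame(self) -> int:
        return self.candidates[0].frame_index

    @property
    def last_frame(self) -> int:
        return self.candidates[-1].frame_index


def _gated_pairs(prev: list[ParticleCandidate], curr: list[ParticleCandidate],
                 params: LinkParams, elapsed: list[int]) -> list[tuple]:
    """All gate-passing (distance, tie-breaks, i, j) pairs, sorted
    deterministically: smaller predicted distance first, then smaller curr
    x, then smaller curr y (then prev x/y)."""
    pairs = []
    for i, p in enumerate(prev):
        pred = (p.centroid[0] + params.expected_flow_dx_px * elapsed[i],
                p.centroid[1])
        for j, c in enumerate(curr):
            dy = abs(c.centroid[1] - p.centroid[1])
            if dy > params.max_lateral_dy_px:
                continue
            # the particle may have paused (pump off): accept anything
            # between no displacement and the full predicted displacement
            d_pred = np.hypot(c.centroid[0] - pred[0], c.centroid[1] - pred[1])
            d_stay = np.hypot(c.centroid[0] - p.centroid[0], dy)
            d = min(d_pred, d_stay)
            if d > params.max_link_distance_px:
                continue
            ratio = c.feret_max_px / max(p.feret_max_px, 1e-9)
            if not (1.0 / params.max_ratio_change <= ratio <= params.max_ratio_change):
                continue
            pairs.append((round(float(d), 9), c.centroid[0], c.centroid[1],
                          p.centroid[0], p.centroid[1], i, j))
    pairs.sort()
    return pairs


def link_frames(prev: list[ParticleCandidate], curr: list[ParticleCandidate],
                params: LinkParams | None = None,
                elapsed: list[int] | None = None) -> list[tuple[int, int]]:
    """One-to-one partial matching between consecutive-frame candidates.

    Greedy over gate-passing pairs in order of distance from the
    flow-predicted position, with deterministic tie-breaks, so the result
    is invariant to the input ordering of the candidates.  ``elapsed``
    gives, per prev candidate, the number of frames since it was last seen
    (1 for a direct predecessor; >1 across detection gaps).

    Returns matched index pairs ``(i_prev, j_curr)``.
    """
    params = params or LinkParams()
    elapsed = elapsed or [1] * len(prev)
    matches: list[tuple[int, int]] = []
    used_prev: set[int] = set()
    used_curr: set[int] = set()
    for *_key, i, j in _gated_pairs(prev, curr, params, elapsed):
        if i in used_prev or j in used_curr:
            continue
        used_prev.add(i)
        used_curr.add(j)
        matches.append((i, j))
    return matches


def count_events(tracks: list[Track], window: DetectionWindow) -> list[Track]:
    """Mark each finished track counted exactly once.

    A track is counted when its representative candidate's centroid fell
    inside the detection window (always true for window-gated candidates).
    Returns the counted tracks, ordered by first frame then track id.
    """
    counted = []
    for tr in tracks:
        if not tr.candidates:
            continue
        rep = tr.representative
        if window.contains(*rep.centroid):
            tr.counted = True
            counted.append(tr)
    counted.sort(key=lambda t: (t.first_frame, t.track_id))
    return counted


class Tracker:
    """Streaming tracker: feed per-frame candidate lists, then finalize.

    Active tracks unmatched on a frame age by one gap frame and are retired
    once their gap exceeds ``max_gap_frames`` (default 2, enough to bridge
    pump pauses combined with the displacement gate).
    """

    def __init__(self, params: LinkParams | None = None):
        self.params = params or LinkParams()
        self.active: list[Track] = []
        self.finished: list[Track] = []
        self._next_id = 0
        self._last_frame: int | None = None

    def step(self, frame_index: int, candidates: list[ParticleCandidate]) -> None:
        prev = [tr.last for tr in self.active]
        elapsed = [frame_index - tr.last_frame for tr in self.active]
        matches = link_frames(prev, candidates, self.params, elapsed)
        matched_prev = {i for i, _ in matches}
        matched_curr = {j for _, j in matches}
        for i, j in matches:
            self.active[i].candidates.append(candidates[j])
            self.active[i].missed = 0
        still_active = []
        for i, tr in enumerate(self.active):
            if i in matched_prev:
                still_active.append(tr)
                continue
            tr.missed += 1
            if tr.missed > self.params.max_gap_frames:
                self.finished.append(tr)
            else:
                still_active.append(tr)
        self.active = still_active
        for j, cand in enumerate(candidates):
            if j in matched_curr:
                continue
            tr = Track(track_id=self._next_id, candidates=[cand])
            self._next_id += 1
            self.active.append(tr)
        self._last_frame = frame_index

    def finalize(self) -> list[Track]:
        """End of video: every active track terminates."""
        self.finished.extend(self.active)
        self.active = []
        self.finished.sort(key=lambda t: t.track_id)
        return self.finished
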