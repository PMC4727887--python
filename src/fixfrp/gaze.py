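"""Dispersion-based fixation detection (I-DT style) and location labelling.

Consecutive gaze samples belong to one fixation while they all stay inside a
circle of a fixed diameter in visual angle anchored at the running centroid;
runs shorter than a temporal threshold are discarded.  Each detected fixation
is then labelled by whether its centroid falls inside the circular area around
the target object, around any other object, or on the blank background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import GazeStream, ObjectLayout


@dataclass
class Fixation:
    onset_ms: float
    duration_ms: float
    centroid: tuple[float, float]
    n_samples: int
    label: str = "unlabelled"


def detect_fixations(
    stream: GazeStream,
    dispersion_deg: float = 2.0,
    min_duration_ms: float = 60.0,
    px_per_deg: float = 40.0,
    max_gap_samples: int = 1,
) -> list[Fixation]:
    """Group consecutive valid samples into fixations.

    ``dispersion_deg`` is the DIAMETER of the grouping circle; a sample joins
    the current run if it lies within half that diameter (in px) of the run's
    centroid, recomputed as samples accrue.  Runs spanning fewer than
    ``min_duration_ms`` (duration = n_samples / fs) are discarded.  Up to
    ``max_gap_samples`` consecutive invalid samples inside a run are tolerated;
    longer gaps break the run.
    """
    if px_per_deg <= 0:
        raise ValueError("px_per_deg must be positive")
    n = len(stream)
    if n == 0 or not stream.valid.any():
        return []
    radius_px = 0.5 * dispersion_deg * px_per_deg
    min_samples = max(2, int(np.ceil(min_duration_ms * stream.fs_gaze / 1000.0)))
    xy = np.column_stack([stream.x_px, stream.y_px])
    valid = np.asarray(stream.valid, dtype=bool)

    fixations: list[Fixation] = []
    i = 0
    while i < n:
        if not valid[i]:
            i += 1
            continue
        members = [i]
        j = i + 1
        gap = 0
        while j < n:
            if not valid[j]:
                gap += 1
                if gap > max_gap_samples:
                    break
                j += 1
                continue
            cand = members + [j]
            pts = xy[cand]
            centroid = pts.mean(axis=0)
            if np.max(np.linalg.norm(pts - centroid, axis=1)) <= radius_px:
                members = cand
                gap = 0
                j += 1
            else:
                break
        if len(members) >= min_samples:
            pts = xy[members]
            centroid = pts.mean(axis=0)
            fixations.append(
                Fixation(
                    onset_ms=float(stream.t_ms[members[0]]),
                    duration_ms=len(members) / stream.fs_gaze * 1000.0,
                    centroid=(float(centroid[0]), float(centroid[1])),
                    n_samples=len(members),
                )
            )
            i = members[-1] + 1
        else:
            i += 1
    return fixations


def label_fixations(
    fixations: list[Fixation],
    layout: ObjectLayout,
    onto_object_radius_deg: float = 2.5,
    px_per_deg: float = 40.0,
) -> list[Fixation]:
    """Label each fixation by its location: within ``onto_object_radius_deg``
    (a RADIUS) of the target center -> target; of any other center ->
    nontarget; otherwise background.  If a centroid falls inside two object
    circles the nearest center wins."""
    radius_px = onto_object_radius_deg * px_per_deg
    centers = layout.object_centers
    out = []
    for fx in fixations:
        d = np.linalg.norm(centers - np.asarray(fx.centroid), axis=1)
        nearest = int(np.argmin(d))
        if d[nearest] <= radius_px:
            label = "target" if nearest == layout.target_index else "nontarget"
        else:
            label = "background"
        out.append(
            Fixation(fx.onset_ms, fx.duration_ms, fx.centroid, fx.n_samples, label)
        )
    return out


def write_fixations_tsv(fixations: list[Fixation], path) -> None:
    pd.DataFrame(
        {
            "onset_ms": [f.onset_ms for f in fixations],
            "duration_ms": [f.duration_ms for f in fixations],
            "cx_px": [f.centroid[0] for f in fixations],
            "cy_px": [f.centroid[1] for f in fixations],
            "n_samples": [f.n_samples for f in fixations],
            "label": [f.label for f in fixations],
        }
    ).to_csv(path, sep="\t", index=False)


def read_fixations_tsv(path) -> list[Fixation]:
    df = pd.read_csv(path, sep="\t")
    return [
        Fixation(r.onset_ms, r.duration_ms, (r.cx_px, r.cy_px), int(r.n_samples), r.label)
        for r in df.itertuples()
    ]
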