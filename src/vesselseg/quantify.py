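"""Vessel-density quantification for longitudinal follow-up.

The statistic is the ratio of vessel pixels to the excess of non-vessel
pixels over vessel pixels, R = N_v / (N_non − N_v), computed inside the
FOV.  Tracking R across consecutive visits flags vascular constriction
(decreasing R); a signed change map localises appearing/disappearing
vessels after segmentation.

Note the denominator is deliberately N_non − N_v rather than the plain
N_v / N_non ratio; ``plain_ratio=True`` switches to the latter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["QuantReport", "vessel_ratio", "ratio_trend", "change_map"]


@dataclass
class QuantReport:
    n_vessel: int
    n_nonvessel: int
    r_vessel: float
    visit_id: str = ""
    subject_id: str = ""

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "visit_id": self.visit_id,
            "n_vessel": self.n_vessel,
            "n_nonvessel": self.n_nonvessel,
            "r_vessel": self.r_vessel,
        }


def vessel_ratio(mask, fov=None, *, plain_ratio: bool = False,
                 visit_id: str = "", subject_id: str = "") -> QuantReport:
    """Compute the vessel-density ratio of a binary mask.

    ``r = n_vessel / (n_nonvessel - n_vessel)`` (or ``n_vessel /
    n_nonvessel`` with ``plain_ratio``), with counts restricted to the
    FOV when one is supplied.  An empty mask yields r = 0.
    """
    mask = np.asarray(mask)
    if not np.isin(np.unique(mask), (0, 1)).all():
        raise ValueError("mask must be binary")
    mask = mask.astype(bool)
    if fov is not None:
        fov = np.asarray(fov).astype(bool)
        if fov.shape != mask.shape:
            raise ValueError("fov not aligned to mask")
        mask = mask[fov]
    n_v = int(mask.sum())
    n_non = int(mask.size - n_v)
    denom = n_non if plain_ratio else n_non - n_v
    if n_v == 0:
        r = 0.0
    elif denom <= 0:
        raise ZeroDivisionError(
            f"vessel ratio undefined: N_non - N_v = {n_non - n_v} <= 0")
    else:
        r = n_v / denom
    return QuantReport(n_v, n_non, r, visit_id=visit_id, subject_id=subject_id)


def ratio_trend(reports) -> list[dict]:
    """Deltas of r_vessel between consecutive visit reports.

    Returns one entry per consecutive pair with the delta and its sign
    (negative deltas are consistent with vascular constriction).
    """
    out = []
    for prev, cur in zip(reports, reports[1:]):
        delta = cur.r_vessel - prev.r_vessel
        out.append({
            "from_visit": prev.visit_id,
            "to_visit": cur.visit_id,
            "delta": delta,
            "sign": int(np.sign(delta)),
        })
    return out


def change_map(mask_prev, mask_next) -> np.ndarray:
    """Signed vessel change between two visits: +1 appeared, −1 disappeared."""
    prev = np.asarray(mask_prev).astype(np.int8)
    nxt = np.asarray(mask_next).astype(np.int8)
    if prev.shape != nxt.shape:
        raise ValueError("masks must share a shape")
    return nxt - prev
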