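"""TF footprint aggregation from insertion tracks.

Per-base insertion counts are stacked over all occurrences of a motif,
minus-strand sites reversed so the motif reads left-to-right, and averaged
into a profile of length 2W + L. Footprint depth is mean(flank) minus
mean(core): a bound TF protects its core from transposition, so deeper
footprints mean more occupancy. Dividing by the flank mean makes depths
comparable across timepoints with different global accessibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from chromdyn.io import InsertionTrack, MotifHit


@dataclass
class FootprintProfile:
    motif_id: str
    label: str
    profile: np.ndarray         # mean insertions/site/bp, length 2W + L
    n_sites: int
    n_skipped: int
    window: int
    motif_length: int

    @property
    def depth(self) -> float:
        return footprint_depth(self)[0]


def aggregate_footprint(
    track: InsertionTrack,
    hits: list[MotifHit],
    window: int = 100,
) -> FootprintProfile:
    """Mean per-base insertion profile around one motif's occurrences.

    Sites whose extended window leaves the covered coordinates are skipped
    and counted in ``n_skipped``.
    """
    if not hits:
        raise ValueError("no hits to aggregate")
    motif_ids = {h.motif_id for h in hits}
    if len(motif_ids) > 1:
        raise ValueError(f"hits from multiple motifs: {sorted(motif_ids)}")
    L = len(hits[0].interval)
    rows, skipped = [], 0
    for h in hits:
        iv = h.interval
        if len(iv) != L:
            raise ValueError("hits of one motif must share a length")
        try:
            w = track.window(iv.chrom, iv.start - window, iv.end + window)
        except KeyError:
            skipped += 1
            continue
        w = np.asarray(w, dtype=float)
        if h.strand == "-":
            w = w[::-1]
        rows.append(w)
    if not rows:
        raise ValueError("zero usable sites after window extension")
    profile = np.mean(rows, axis=0)
    return FootprintProfile(
        motif_id=hits[0].motif_id,
        label=track.label,
        profile=profile,
        n_sites=len(rows),
        n_skipped=skipped,
        window=window,
        motif_length=L,
    )


def footprint_depth(
    profile: FootprintProfile, flank_margin: int = 20
) -> tuple[float, np.ndarray | None]:
    """(depth, flank-normalized profile).

    core = the central L positions; flank = the outermost ``flank_margin``
    positions on each side; depth = mean(flank) - mean(core). The
    normalized profile is profile / mean(flank), or None when the flank
    mean is zero.
    """
    if profile.window <= flank_margin:
        raise ValueError("window must exceed flank_margin")
    p = profile.profile
    W, L = profile.window, profile.motif_length
    core = p[W : W + L]
    flank = np.concatenate([p[:flank_margin], p[-flank_margin:]])
    depth = float(flank.mean() - core.mean())
    if flank.mean() == 0:
        return depth, None
    return depth, p / flank.mean()


def normalized_depth(profile: FootprintProfile, flank_margin: int = 20) -> float:
    """Depth on the flank-normalized profile (dimensionless occupancy proxy)."""
    depth, norm = footprint_depth(profile, flank_margin)
    if norm is None:
        return float("nan")
    W, L = profile.window, profile.motif_length
    return float(
        np.concatenate([norm[:flank_margin], norm[-flank_margin:]]).mean()
        - norm[W : W + L].mean()
    )


def footprint_timecourse(
    tracks: dict[int, InsertionTrack],
    hits: list[MotifHit],
    window: int = 100,
    flank_margin: int = 20,
) -> tuple[dict[int, FootprintProfile], pd.DataFrame]:
    """One profile per timepoint over a shared hit set, plus a depth table."""
    missing = [d for d, t in tracks.items() if t is None]
    if missing:
        raise ValueError(f"missing tracks for timepoints: {missing}")
    profiles, rows = {}, []
    for d in sorted(tracks):
        prof = aggregate_footprint(tracks[d], hits, window)
        profiles[d] = prof
        depth, _ = footprint_depth(prof, flank_margin)
        rows.append(
            {
                "timepoint": d,
                "depth": depth,
                "normalized_depth": normalized_depth(prof, flank_margin),
                "n_sites": prof.n_sites,
            }
        )
    return profiles, pd.DataFrame(rows).set_index("timepoint")
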