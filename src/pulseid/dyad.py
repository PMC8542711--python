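"""Encounter-level statistics for dyadic agonistic interactions.

Dominance within a pairing is decided by attack counts from manually scored
video annotations; exact one-sided binomial tests relate dominance and
attack initiation to the body-size difference (size classes split at a 20%
length difference); electric-image time courses up to the first physical
contact ask whether the fish that initiated the approach is the one
predicted to have detected its contender first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bem import first_detection

__all__ = [
    "EncounterAnnotation",
    "DominanceResult",
    "dominance",
    "binom_onesided",
    "ei_timecourse",
    "approach_predictor_summary",
    "load_annotations",
]

SIZE_CLASS_THRESHOLD_PCT = 20.0


@dataclass
class EncounterAnnotation:
    """Manually scored events of one dyadic encounter."""

    pair_id: object
    fish_lengths: dict                 # fish id -> length cm
    first_contact_time: float
    initiator_id: object
    target_region: str = "head"        # head | tail
    attack_events: list = field(default_factory=list)   # (time s, actor id)
    chase_intervals: list = field(default_factory=list)  # (start, end, chaser)

    def __post_init__(self):
        if len(self.fish_lengths) != 2:
            raise ValueError("an encounter involves exactly 2 fish")
        ids = set(self.fish_lengths)
        for t, actor in self.attack_events:
            if actor not in ids:
                raise ValueError(f"attack actor {actor!r} not in the pair")

    @property
    def size_difference_pct(self) -> float:
        lo, hi = sorted(self.fish_lengths.values())
        return 100.0 * (hi - lo) / hi

    @property
    def size_class(self) -> str:
        """"large" for >20% length difference, else "small"."""
        return ("large" if self.size_difference_pct > SIZE_CLASS_THRESHOLD_PCT
                else "small")

    @property
    def larger_id(self):
        return max(self.fish_lengths, key=self.fish_lengths.get)


@dataclass
class DominanceResult:
    dominant_id: object                # None when undetermined
    attack_counts: dict
    size_difference_pct: float
    size_class: str

    @property
    def determined(self) -> bool:
        return self.dominant_id is not None


def dominance(ann: EncounterAnnotation) -> DominanceResult:
    """Dominant = the fish with strictly more attacks; ties are undetermined."""
    counts = {i: 0 for i in ann.fish_lengths}
    for _, actor in ann.attack_events:
        counts[actor] += 1
    ids = sorted(counts)
    if counts[ids[0]] == counts[ids[1]]:
        dominant = None
    else:
        dominant = max(counts, key=counts.get)
    return DominanceResult(dominant, counts, ann.size_difference_pct,
                           ann.size_class)


def binom_onesided(k: int, n: int, p0: float = 0.5) -> float:
    """Exact upper-tail binomial probability P(X >= k | n, p0).

    Reproduces the printed test values of the encounter analysis, e.g.
    5/5 -> 0.03125, 9/13 -> 0.1334, 4/8 -> 0.6367.
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError("need n >= 1 and 0 <= k <= n")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must lie in [0, 1]")
    return float(stats.binom.sf(k - 1, n, p0))


def ei_timecourse(records, ei_summaries: pd.DataFrame, distances=None,
                  first_contact_time: float | None = None,
                  factor: float = 2.0, floor: float = 0.1):
    """Per-pair EI time course up to first contact, plus the divergence time.

    ``records`` are assignment records ordering the EODs; ``ei_summaries``
    must hold one row per assigned EOD (columns: eod_time_s, emitter,
    active_max, active_rms, passive_max, passive_rms); ``distances`` is an
    optional matching sequence of inter-fish anchor distances (cm).  Returns
    ``(table, detection)`` where detection is the first-detection verdict
    computed from the passive maxima.
    """
    times = [r.eod_time for r in records
             if first_contact_time is None or r.eod_time <= first_contact_time]
    table = ei_summaries[ei_summaries["eod_time_s"].isin(times)].copy()
    missing = set(np.round(times, 9)) - set(np.round(
        table["eod_time_s"].to_numpy(), 9))
    if missing:
        raise ValueError(
            f"{len(missing)} assigned EODs lack an EI summary")
    table = table.sort_values("eod_time_s", kind="stable").reset_index(
        drop=True)
    if distances is not None:
        table["interfish_distance_cm"] = np.asarray(distances, dtype=float)
    fish_ids = sorted(table["emitter"].unique())
    detection = None
    if len(fish_ids) == 2:
        # passive EI received by a fish comes from the *other* fish's EODs
        a, b = fish_ids
        series_a = table.loc[table["emitter"] == b,
                             ["eod_time_s", "passive_max"]].to_numpy()
        series_b = table.loc[table["emitter"] == a,
                             ["eod_time_s", "passive_max"]].to_numpy()
        if len(series_a) and len(series_b):
            detection = first_detection(series_a, series_b, factor, floor,
                                        ids=(a, b))
    return table, detection


def approach_predictor_summary(pairs) -> dict:
    """Does the approach initiator coincide with the predicted first detector?

    ``pairs`` is a list of dicts with keys ``initiator_id``,
    ``passive_first`` and ``active_first`` (fish ids or None) and
    ``size_class``.  Counts matches per modality (overall and per size
    class) with one-sided exact binomial p-values against chance.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty pair list")

    def tally(subset, key):
        decided = [p for p in subset if p.get(key) is not None]
        k = sum(1 for p in decided if p[key] == p["initiator_id"])
        n = len(decided)
        return {"matches": k, "n": n,
                "p_value": binom_onesided(k, n) if n else np.nan}

    out = {}
    for modality in ("passive", "active"):
        key = f"{modality}_first"
        out[modality] = tally(pairs, key)
        for cls in ("large", "small"):
            sub = [p for p in pairs if p.get("size_class") == cls]
            if sub:
                out[f"{modality}_{cls}"] = tally(sub, key)
    return out


def load_annotations(path) -> list:
    """Read encounter annotations from the documented CSV schema.

    Event rows: pair_id, fish1_id, fish1_length_cm, fish2_id,
    fish2_length_cm, first_contact_time_s, initiator_id, target_region,
    event_type (attack|chase), event_time_s, event_end_s, actor_id.
    """
    df = pd.read_csv(path)
    out = []
    for pair_id, g in df.groupby("pair_id", sort=False):
        head = g.iloc[0]
        lengths = {head["fish1_id"]: float(head["fish1_length_cm"]),
                   head["fish2_id"]: float(head["fish2_length_cm"])}
        attacks, chases = [], []
        for r in g.itertuples():
            if r.event_type == "attack":
                attacks.append((float(r.event_time_s), r.actor_id))
            elif r.event_type == "chase":
                chases.append((float(r.event_time_s), float(r.event_end_s),
                               r.actor_id))
        out.append(EncounterAnnotation(
            pair_id=pair_id, fish_lengths=lengths,
            first_contact_time=float(head["first_contact_time_s"]),
            initiator_id=head["initiator_id"],
            target_region=head.get("target_region", "head"),
            attack_events=attacks, chase_intervals=chases))
    return out
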