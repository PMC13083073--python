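"""The predefined 40-electrode-pair set and hemisphere categorization.

The pair set spans fronto-temporal, fronto-parietal, centro-parietal and
temporo-occipital connections chosen a priori to limit the multiple-comparison
burden of sensor-space connectivity. Category follows 10-20 suffix parity of
both members: both left -> ``left_intra``, both right -> ``right_intra``,
mixed -> ``inter``. Midline electrodes have no category in this scheme.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .montage import Montage

__all__ = ["PairSet", "classify_pairs", "DEFAULT_PAIRS", "default_pairset"]

# the 40 predefined pairs, in canonical listed order
DEFAULT_PAIRS: list[tuple[str, str]] = [
    ("F3", "T7"), ("F3", "T8"), ("F4", "T7"), ("F4", "T8"),
    ("F3", "P3"), ("F3", "P4"), ("F4", "P3"), ("F4", "P4"),
    ("F3", "TP7"), ("F3", "TP8"), ("F4", "TP7"), ("F4", "TP8"),
    ("F3", "P7"), ("F3", "P8"), ("F4", "P7"), ("F4", "P8"),
    ("F3", "O1"), ("F3", "O2"), ("F4", "O1"), ("F4", "O2"),
    ("C3", "T7"), ("C3", "T8"), ("C4", "T7"), ("C4", "T8"),
    ("C3", "P3"), ("C3", "P4"), ("C4", "P3"), ("C4", "P4"),
    ("C3", "TP7"), ("C3", "TP8"), ("C4", "TP7"), ("C4", "TP8"),
    ("C3", "P7"), ("C3", "P8"), ("C4", "P7"), ("C4", "P8"),
    ("C3", "O1"), ("C3", "O2"), ("C4", "O1"), ("C4", "O2"),
]


@dataclass
class PairSet:
    pairs: list[tuple[str, str]]
    category: list[str]  # per pair: left_intra | right_intra | inter

    def __post_init__(self) -> None:
        if len(self.pairs) != len(self.category):
            raise ValueError("pairs and category lengths differ")
        seen = set()
        for p in self.pairs:
            key = frozenset(p)
            if key in seen:
                raise ValueError(f"duplicate pair {p}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def names(self) -> list[str]:
        return [f"{a}-{b}" for a, b in self.pairs]

    def counts(self) -> dict[str, int]:
        return dict(Counter(self.category))

    def electrodes(self) -> list[str]:
        out: list[str] = []
        for a, b in self.pairs:
            for e in (a, b):
                if e not in out:
                    out.append(e)
        return out

    def of_category(self, category: str) -> list[tuple[str, str]]:
        return [p for p, c in zip(self.pairs, self.category) if c == category]


def classify_pairs(pairs: list[tuple[str, str]], montage: Montage) -> PairSet:
    """Assign a hemisphere category to every electrode pair.

    Raises if an electrode is not in the montage or if a pair contains a
    midline electrode (the left/right/inter scheme leaves it undefined).
    """
    categories: list[str] = []
    for a, b in pairs:
        ha = montage.hemisphere[montage.index(a)]
        hb = montage.hemisphere[montage.index(b)]
        if "midline" in (ha, hb):
            raise ValueError(f"pair ({a}, {b}) contains a midline electrode; category undefined")
        if ha == hb:
            categories.append("left_intra" if ha == "left" else "right_intra")
        else:
            categories.append("inter")
    return PairSet(list(pairs), categories)


def default_pairset(montage: Montage | None = None) -> PairSet:
    from .montage import load_montage

    return classify_pairs(DEFAULT_PAIRS, montage or load_montage("default30"))
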