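"""Deterministic generators of valid codes and worked-example corpora.

Nothing here touches the network: random corpora are drawn uniformly over
the digit space (with rejection sampling to hit a requested
oligomannose/hybrid/complex mix) and the worked-example corpus is the small
set of identifiers used throughout the documentation.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .codec import GlycanCode, classify, parse_code

__all__ = ["FixtureSpec", "random_codes", "reference_corpus", "write_random_code_file"]

_CLASSES = ("oligomannose", "hybrid", "complex")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a reproducible random corpus.

    ``class_mix`` gives sampling proportions over the three structural
    classes; they must be non-negative and sum to 1.  ``blank_rate`` is the
    probability of interleaving a blank line when writing code files.
    """

    seed: int = 0
    n: int = 100
    class_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "oligomannose": 0.2,
            "hybrid": 0.2,
            "complex": 0.6,
        }
    )
    blank_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if set(self.class_mix) - set(_CLASSES):
            raise ValueError(f"class_mix keys must be among {_CLASSES}")
        total = sum(self.class_mix.values())
        if any(v < 0 for v in self.class_mix.values()) or abs(total - 1) > 1e-9:
            raise ValueError("class_mix must be non-negative and sum to 1")
        if not 0 <= self.blank_rate < 1:
            raise ValueError("blank_rate must be in [0, 1)")


def _random_code_of_class(rng: random.Random, cls: str) -> GlycanCode:
    # rejection sampling over the digit space; every class has plenty of
    # mass, so this terminates quickly
    while True:
        code = GlycanCode.from_digits(
            rng.randint(3, 6),
            rng.randint(0, 1),
            rng.randint(0, 1),
            tuple(rng.randint(0, 6) for _ in range(4)),
        )
        if classify(code) == cls:
            return code


def random_codes(spec: FixtureSpec) -> list[GlycanCode]:
    """Draw ``spec.n`` valid codes; identical output for identical spec."""
    rng = random.Random(spec.seed)
    classes = [c for c in _CLASSES if spec.class_mix.get(c, 0) > 0]
    # largest-remainder apportionment so realized class proportions match
    # the requested mix exactly (up to integer rounding), then shuffle
    quotas = {c: spec.class_mix[c] * spec.n for c in classes}
    counts = {c: int(q) for c, q in quotas.items()}
    short = spec.n - sum(counts.values())
    for c in sorted(classes, key=lambda c: quotas[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    labels = [c for c in classes for _ in range(counts[c])]
    rng.shuffle(labels)
    return [_random_code_of_class(rng, cls) for cls in labels]


def write_random_code_file(path: str | Path, spec: FixtureSpec) -> list[GlycanCode]:
    """Write a random corpus as a code-list file, inserting blank lines at
    ``spec.blank_rate``; returns the codes written."""
    codes = random_codes(spec)
    rng = random.Random(spec.seed + 1)
    with open(path, "w", encoding="utf-8") as fh:
        for code in codes:
            while spec.blank_rate and rng.random() < spec.blank_rate:
                fh.write("\n")
            fh.write(str(code) + "\n")
    return codes


def reference_corpus() -> dict[str, tuple[GlycanCode, ...]]:
    """The worked-example identifiers used in the documentation.

    * ``trimannosyl_core`` — the bare Man3 core, 300000000
    * ``triantennary_sialylated`` — fucosylated tri-sialylated
      triantennary structure, 310033333
    * ``tetraantennary_lacnac_variants`` — the four sialylation placements
      of the A4G4FLac1S3 composition
    """
    return {
        "trimannosyl_core": (parse_code("300000000"),),
        "triantennary_sialylated": (parse_code("310033333"),),
        "tetraantennary_lacnac_variants": (
            parse_code("310333553"),
            parse_code("310332653"),
            parse_code("310323653"),
            parse_code("310233653"),
        ),
    }
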