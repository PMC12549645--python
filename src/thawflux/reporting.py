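"""Report writers, provenance records and small presentation helpers.

Includes the quartile-based line-weight binning used to draw metabolic
pathway maps: a gene's relative abundance (%) maps to one of four line
classes (dotted/thin/medium/thick) split at the quartile breakpoints of
the abundance distribution.
"""

from __future__ import annotations

import hashlib
import json
import math
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Sequence

WEIGHT_LABELS = ("dotted", "thin", "medium", "thick")
DEFAULT_BREAKPOINTS = (10.04, 17.38, 21.48)


@dataclass(frozen=True)
class WeightClass:
    """One line-weight class covering [lower, upper) percent abundance."""

    label: str
    lower: float
    upper: float  # math.inf for the open top class


def weight_classes(
    breakpoints: Sequence[float] = DEFAULT_BREAKPOINTS,
) -> tuple[WeightClass, ...]:
    """The four classes partitioning [0, 100] at the given breakpoints."""
    bp = list(breakpoints)
    if len(bp) != 3 or any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
        raise ValueError("breakpoints must be three strictly increasing values")
    if bp[0] <= 0 or bp[-1] >= 100:
        raise ValueError("breakpoints must lie strictly inside (0, 100)")
    edges = [0.0, *bp, math.inf]
    return tuple(
        WeightClass(label, lo, hi)
        for label, lo, hi in zip(WEIGHT_LABELS, edges[:-1], edges[1:])
    )


def classify_pathway_weight(
    rel_abundance: float,
    breakpoints: Sequence[float] = DEFAULT_BREAKPOINTS,
) -> str:
    """Line-weight label for a relative abundance in percent.

    Intervals are half-open [lower, upper): a value exactly at a
    breakpoint belongs to the upper class.  Every abundance in [0, 100]
    maps to exactly one class.
    """
    if not 0.0 <= rel_abundance <= 100.0:
        raise ValueError(f"relative abundance must be in [0, 100] (got {rel_abundance})")
    for cls in weight_classes(breakpoints):
        if cls.lower <= rel_abundance < cls.upper:
            return cls.label
    return WEIGHT_LABELS[-1]  # rel_abundance == upper bound of the top finite edge


def _round_sig(value: float, sig: int) -> float:
    if value == 0 or not math.isfinite(value):
        return value
    return round(value, sig - 1 - int(math.floor(math.log10(abs(value)))))


def round_floats(obj: Any, sig: int = 6) -> Any:
    """Recursively round floats to ``sig`` significant digits for reports."""
    if isinstance(obj, float):
        return _round_sig(obj, sig)
    if isinstance(obj, dict):
        return {k: round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [round_floats(v, sig) for v in obj]
    return obj


def provenance_record(config: Any, seed: int | None = None) -> dict:
    """Machine-readable record of what produced an output file."""
    import thawflux

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "package": "thawflux",
        "version": thawflux.__version__,
        "python": platform.python_version(),
        "seed": seed,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "config": config,
    }


def write_json_report(
    path: str | Path,
    payload: dict,
    config: Any = None,
    seed: int | None = None,
    sig_digits: int = 6,
    full_precision: bool = False,
) -> Path:
    """Write a JSON report with rounded presentation values.

    Floats are serialised with ``sig_digits`` significant digits unless
    ``full_precision`` is set; a provenance record is attached when a
    config is given.
    """
    path = Path(path)
    out = dict(payload)
    if config is not None:
        out["provenance"] = provenance_record(config, seed)
    if not full_precision:
        out = round_floats(out, sig_digits)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(out, indent=2, default=str) + "\n")
    return path
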