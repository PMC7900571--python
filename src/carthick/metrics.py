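"""Segmentation agreement: Dice similarity coefficient and per-structure reports."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .volume import InputError, LabelMask


def dice(reference: LabelMask, candidate: LabelMask) -> float:
    """Dice similarity coefficient DSC(A, B) = 2|A∩B| / (|A| + |B|).

    Ranges over [0, 1]; higher is better agreement. Two empty masks agree
    perfectly by convention (returns 1.0, avoiding 0/0).
    """
    reference.check_compatible(candidate)
    a = reference.voxels
    b = candidate.voxels
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def dice_report(pairs: dict[str, list[tuple[LabelMask, LabelMask]]]) -> pd.DataFrame:
    """Per-structure mean ± sample-SD DSC over subjects.

    ``pairs`` maps structure name → list of (reference, candidate) mask
    pairs, one per subject. Returns a DataFrame indexed by structure with
    columns ``mean``, ``sd``, ``n`` and a 4-decimal ``formatted`` column
    ("mean ± sd"). SD is NaN for a single subject.
    """
    if not pairs or all(len(v) == 0 for v in pairs.values()):
        raise InputError("dice_report needs at least one mask pair")
    rows = []
    for structure, pairlist in pairs.items():
        if not pairlist:
            raise InputError(f"no mask pairs for structure {structure!r}")
        scores = np.array([dice(ref, cand) for ref, cand in pairlist])
        mean = float(scores.mean())
        sd = float(scores.std(ddof=1)) if len(scores) > 1 else float("nan")
        rows.append(
            {
                "structure": structure,
                "mean": mean,
                "sd": sd,
                "n": len(scores),
                "formatted": f"{mean:.4f} ± {sd:.4f}",
            }
        )
    return pd.DataFrame(rows).set_index("structure")
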