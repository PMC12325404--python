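"""Seeded synthetic fixture tables for tests and examples.

All fixtures are generated programmatically from recorded seeds; nothing is
shipped on disk.  The ``toy`` table is small enough to summarize by hand.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import ModelVariant
from .simulate import DesignSpec, draw_parameters, simulate_trials

__all__ = ["make_fixtures", "toy_trials"]


def toy_trials() -> pd.DataFrame:
    """Two-statement hand-computable table.

    Statement "A": new judgments 1,0,1,0 (N = 0.5); repeated 1,1,1,0
    (R = 0.75) -> truth effect 0.25, perceived-truth mean 0.625.
    Statement "B": new 0,0 (N = 0); repeated 1,1 (R = 1).
    """
    rows = []
    for k, j in enumerate([1, 0, 1, 0]):
        rows.append((f"P{k}", "A", 0, j))
    for k, j in enumerate([1, 1, 1, 0]):
        rows.append((f"P{k + 4}", "A", 1, j))
    for k, j in enumerate([0, 0]):
        rows.append((f"P{k}", "B", 0, j))
    for k, j in enumerate([1, 1]):
        rows.append((f"P{k + 4}", "B", 1, j))
    return pd.DataFrame(rows, columns=["participant_id", "statement_id", "repeated", "judgment"])


def make_fixtures(rng=None, n_statements: int = 20, n_participants: int = 40, m: float = 0.4) -> dict[str, pd.DataFrame]:
    """One seeded trial table per model variant plus the hand-computable toy."""
    seed_seq = np.random.SeedSequence(0 if rng is None else np.random.default_rng(rng).integers(2**31))
    out: dict[str, pd.DataFrame] = {"toy": toy_trials()}
    for variant, child in zip(ModelVariant, seed_seq.spawn(4)):
        sub = np.random.default_rng(child)
        design = DesignSpec(
            n_statements=n_statements, n_participants=n_participants,
            sigma_u=0.3, sigma_v=0.1,
        )
        params = draw_parameters(design, variant, m, sub)
        out[variant.name] = simulate_trials(design, params, sub)
    return out
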