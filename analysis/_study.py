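"""Shared study definition for the numbered analysis scripts.

One cohort of 37 TBI subjects and 13 controls (the scale typical of
single-site subacute-TBI imaging studies), imaged on a desk-scale
phantom grid with 24 directions per shell at SNR 50. Every script
regenerates what it needs from this spec — the generators are pure
functions of (spec, seed), so the stages stay independently runnable.
"""

from pathlib import Path

from dtialps.synthdata import CohortSpec, PhantomSpec

RESULTS = Path(__file__).resolve().parent.parent / "results"

MASTER_SEED = 20230501


def phantom_base() -> PhantomSpec:
    return PhantomSpec(
        grid_shape=(32, 32, 16),
        n_dirs_per_shell=24,
        n_b0=3,
        noise_sigma=0.02,
    )


def cohort_spec() -> CohortSpec:
    return CohortSpec(n_tbi=37, n_control=13, seed=MASTER_SEED)
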