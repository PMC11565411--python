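"""The full-scale screen scenario: study-sized library, pools and truth.

The screen modelled here has fixed dimensions: a 4,488-member candidate
library divided into 136 pools of 33 members grouped into 34 super-pools,
screened against 109 TCR avatars, of which nine react to 13 distinct
members with potencies from 20 nM to 20 uM.

The external binding predictor that produced the original 4,488-member
selection is not part of this package; the scenario instead keeps the
4,488 strongest distinct junction-spanning candidates under the packaged
surrogate scorer, which reproduces the screen's dimensions exactly while
leaving the member identities synthetic.
"""

from __future__ import annotations

from .deconvolution import ScreenPolicy, run_deconvolution
from .library import (
    BindingPredictor,
    Library,
    SurrogatePwmPredictor,
    deduplicate,
    enumerate_fusions,
    junction_windows,
    score_candidates,
)
from .pools import PoolManifest, group_superpools, partition_pools
from .proinsulin import canonical_proinsulin, fragment_kmers
from .simulate import NoiseModel, ReactivityTruth, SimulatedScreen, headline_scenario

__all__ = ["paper_scale_library", "paper_scale_manifest", "run_headline_screen"]

LIBRARY_SIZE = 4488
POOL_SIZE = 33
GROUP_SIZE = 4
N_AVATARS = 109


def paper_scale_library(
    n: int = LIBRARY_SIZE, predictor: BindingPredictor | None = None
) -> Library:
    """The ``n`` strongest distinct junction-spanning 12-mer candidates."""
    if predictor is None:
        predictor = SurrogatePwmPredictor()
    fragments = fragment_kmers(canonical_proinsulin(), k=12)
    candidates = []
    for fusion in enumerate_fusions(fragments, allow_self=False):
        candidates.extend(junction_windows(fusion, w=12))
    scored = score_candidates(candidates, predictor)
    lib = deduplicate(scored)
    if len(lib) < n:
        raise ValueError(f"only {len(lib)} distinct candidates available, need {n}")
    ranked = sorted(lib.entries, key=lambda e: (e.score.value, e.sequence))
    kept = {e.sequence for e in ranked[:n]}
    entries = tuple(e for e in lib.entries if e.sequence in kept)  # keeps lexicographic order
    return Library(entries=entries, build_report={"candidates": len(candidates), "library": n})


def paper_scale_manifest(library: Library, seed: int = 0) -> PoolManifest:
    return group_superpools(
        partition_pools(library, pool_size=POOL_SIZE, seed=seed), group_size=GROUP_SIZE
    )


def run_headline_screen(
    seed: int,
    library: Library | None = None,
    noise: NoiseModel | None = None,
    policy: ScreenPolicy | None = None,
):
    """Plant the headline truth in a full-size screen, simulate all three
    stages at the given seed, and deconvolve.

    Returns (truth, result).
    """
    if library is None:
        library = paper_scale_library()
    manifest = paper_scale_manifest(library, seed=seed)
    avatars, truth = headline_scenario(library.member_ids(), n_avatars=N_AVATARS, seed=seed)
    screen = SimulatedScreen(truth, manifest, noise or NoiseModel(), seed=seed)
    result = run_deconvolution(screen, manifest, avatars, policy or ScreenPolicy())
    result.validate_chains(manifest)
    return truth, result
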