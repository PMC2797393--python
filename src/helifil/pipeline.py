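"""End-to-end analysis pipelines composing the individual stages.

The canonical workflow for a two-state filament dataset:

1. preprocess (normalise, optional phase flip, band-pass);
2. sort segments into conformational state groups
   (:func:`helifil.msa.split_states`);
3. within each group, classify into ~15-member classes and average;
4. two-stage helical grid search per group (coarse increments 3.2 A / 2 deg,
   fine 0.5 A / 0.5 deg);
5. optionally reconstruct each state at its refined parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imagio import ImageStack, RunConfig
from .preprocess import preprocess_stack, FilterParams
from .msa import eigen_decompose, classify, class_average, split_states
from .helix_search import (SearchGrid, RefinedParams, ErrorSurface,
                           search_helical_params, COARSE_GRID_DEFAULT)
from .geometry import protomers_per_turn

__all__ = ["StateResult", "TwoStateAnalysis", "analyze_states"]


@dataclass
class StateResult:
    """Per-state outcome of the helical analysis."""

    group: int
    n_segments: int
    class_averages: list[np.ndarray]
    refined: RefinedParams
    coarse_surface: ErrorSurface

    @property
    def pitch(self) -> float:
        return self.refined.params.pitch

    @property
    def twist(self) -> float:
        return self.refined.params.twist

    @property
    def protomers_per_turn(self) -> float:
        return protomers_per_turn(self.twist)[0]


@dataclass
class TwoStateAnalysis:
    state_labels: np.ndarray          # per-image group index
    results: list[StateResult] = field(default_factory=list)


def analyze_states(stack: ImageStack, seed: int,
                   n_states: int = 2,
                   coarse: SearchGrid = COARSE_GRID_DEFAULT,
                   members_per_class: int = 15,
                   filter_params: FilterParams | None = None,
                   preprocess: bool = True,
                   **search_kw) -> TwoStateAnalysis:
    """Run the whole two-state helical analysis on a segment stack.

    Groups are ordered by size (largest first, i.e. the majority state
    leads).  ``search_kw`` is forwarded to the grid search.
    """
    if preprocess:
        stack = preprocess_stack(stack, fp=filter_params)
    grouping = split_states(stack, n_states=n_states, seed=seed)
    sizes = np.bincount(grouping.labels, minlength=n_states)
    order = np.argsort(-sizes)
    analysis = TwoStateAnalysis(state_labels=grouping.labels)
    for group in order:
        members = np.nonzero(grouping.labels == group)[0]
        if len(members) < 2 * members_per_class:
            continue
        sub = ImageStack(images=stack.images[members], pixel_size=stack.pixel_size)
        n_classes = max(2, len(sub) // members_per_class)
        eig = eigen_decompose(sub, n_components=10)
        cls = classify(sub, eig, n_classes=n_classes, seed=seed + 1)
        avgs = [ca.image for ca in class_average(sub, cls)]
        refined, coarse_surface = search_helical_params(
            avgs, stack.pixel_size, coarse=coarse, **search_kw)
        analysis.results.append(StateResult(
            group=int(group), n_segments=len(members), class_averages=avgs,
            refined=refined, coarse_surface=coarse_surface))
    return analysis
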