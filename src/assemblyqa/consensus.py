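"""Score-combination variants: assembling component scores into SCORE,
QSCORE and per-residue confidences.

Three variants are provided.  ``dock`` targets linear correlation with
observed quality: SCORE is the mean of DockQJury and lDDTOfficialJury,
QSCORE the mean of DockQJury and QSscoreOfficialJury, residue confidences
come from ModFOLDIA.  ``dockR`` targets ranking and adds the single-model
voromqa term to each combination.  ``dockS`` is the quasi-single-model
variant: the same global combinations as ``dock`` but scored against an
externally supplied reference model set rather than the population, with
residue confidences from CDA, voromqa and ModFOLDIA.

For populations above 1,500 total residues the all-against-all comparison is
shortcut: models are pre-scored with voromqa and only the top 40 serve as
the jury reference set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .components import (
    AdapterError,
    ComponentScore,
    JuryUndefinedError,
    ReferenceSet,
    cda_score,
    jury_score,
    modfoldia_residue_scores,
    voromqa_score,
)
from .metrics import DEFAULT_PARAMS, MetricParams, UndefinedScoreError
from .structures import StructureModel

__all__ = [
    "VariantConfig",
    "QualityEstimate",
    "PopulationError",
    "LARGE_STRUCTURE_THRESHOLD",
    "TOP_N_REFERENCES",
    "score_population",
    "select_reference_subset",
    "route_by_size",
]

log = logging.getLogger(__name__)

LARGE_STRUCTURE_THRESHOLD = 1500  # total residues above which juries use a subset
TOP_N_REFERENCES = 40             # subset size for the large-structure shortcut

_JURY_COMPONENTS = {
    "DockQJury": "dockq",
    "QSscoreJury": "qs_weighted",
    "QSscoreOfficialJury": "qs_official",
    "lDDTOfficialJury": "oligo_lddt",
}


class PopulationError(RuntimeError):
    """No model in the population could be scored."""


@dataclass(frozen=True)
class VariantConfig:
    """Which component methods feed each of the three output scores."""

    name: str
    fold_components: tuple[str, ...]
    interface_components: tuple[str, ...]
    residue_components: tuple[str, ...]

    @staticmethod
    def variant(name: str) -> "VariantConfig":
        table = {
            "dock": VariantConfig(
                "dock",
                fold_components=("DockQJury", "lDDTOfficialJury"),
                interface_components=("DockQJury", "QSscoreOfficialJury"),
                residue_components=("ModFOLDIA",),
            ),
            "dockR": VariantConfig(
                "dockR",
                fold_components=("QSscoreJury", "lDDTOfficialJury", "voromqa"),
                interface_components=("DockQJury", "QSscoreOfficialJury", "voromqa"),
                residue_components=("voromqa", "ModFOLDIA"),
            ),
            "dockS": VariantConfig(
                "dockS",
                fold_components=("DockQJury", "lDDTOfficialJury"),
                interface_components=("DockQJury", "QSscoreOfficialJury"),
                residue_components=("CDA", "voromqa", "ModFOLDIA"),
            ),
        }
        try:
            return table[name]
        except KeyError:
            raise ValueError(f"unknown variant {name!r}; expected dock, dockR or dockS") from None

    @property
    def all_components(self) -> tuple[str, ...]:
        seen = []
        for name in self.fold_components + self.interface_components + self.residue_components:
            if name not in seen:
                seen.append(name)
        return tuple(seen)


@dataclass
class QualityEstimate:
    """Predicted quality of one model: global fold, interface and residues."""

    model_id: str
    score: float | None
    qscore: float | None
    residue_conf: list[float] | None
    unscored: bool = False
    components: dict[str, ComponentScore] = field(default_factory=dict)


def route_by_size(models: list[StructureModel], variant: VariantConfig,
                  large_threshold: int = LARGE_STRUCTURE_THRESHOLD) -> str:
    """Scoring plan: 'external' (dockS), 'top40' (large) or 'all_against_all'."""
    if variant.name == "dockS":
        return "external"
    if models and max(m.total_residues for m in models) > large_threshold:
        return "top40"
    return "all_against_all"


def select_reference_subset(models: list[StructureModel], n: int,
                            scorer: Callable[[StructureModel], float]) -> ReferenceSet:
    """Top ``n`` models by a single-model scorer, ties broken by model id."""
    if not models:
        raise ValueError("cannot select references from an empty population")
    if n < 1:
        raise ValueError("subset size must be >= 1")
    ranked = sorted(models, key=lambda m: (-scorer(m), m.model_id))
    return ReferenceSet(ranked[: min(n, len(models))], origin="top40")


def _compute_component(name: str, model: StructureModel, refs: ReferenceSet,
                       params: MetricParams,
                       adapter_config: dict | None) -> ComponentScore:
    if name in _JURY_COMPONENTS:
        return jury_score(model, refs, _JURY_COMPONENTS[name], params)
    if name == "ModFOLDIA":
        return modfoldia_residue_scores(model, refs, params)
    if name == "CDA":
        return cda_score(model, refs, params)
    if name == "voromqa":
        return voromqa_score(model, adapter_config, params)
    raise ValueError(f"unknown component {name!r}")


def score_population(models: list[StructureModel], variant: VariantConfig | str,
                     refs: ReferenceSet | None = None,
                     params: MetricParams = DEFAULT_PARAMS,
                     large_threshold: int = LARGE_STRUCTURE_THRESHOLD,
                     top_n: int = TOP_N_REFERENCES,
                     adapter_config: dict | None = None) -> list[QualityEstimate]:
    """Score every model of a population with one consensus variant.

    SCORE / QSCORE / residue confidences are unweighted means of the variant's
    fold / interface / residue component scores.  The jury reference set is
    the population minus the scored model, the voromqa-top-40 subset for
    populations above ``large_threshold`` total residues, or — for the
    quasi-single-model variant dockS — the externally supplied ``refs``.
    Components that fail for one model are dropped from that model's mean
    with a logged warning; models where everything fails are returned flagged
    ``unscored``.
    """
    if isinstance(variant, str):
        variant = VariantConfig.variant(variant)
    if not models:
        raise ValueError("empty model population")
    if variant.name == "dockS":
        if refs is None:
            raise ValueError("variant dockS requires an external reference set")
    elif refs is None and len(models) < 2:
        raise ValueError("clustering variants need at least 2 models")

    plan = route_by_size(models, variant, large_threshold)
    prescore: dict[str, float] = {}
    if plan == "top40":
        prescore = {m.model_id: voromqa_score(m, adapter_config, params).global_value
                    for m in models}
        log.info("large-structure shortcut: jury references = top %d of %d by voromqa",
                 min(top_n, len(models) - 1), len(models))

    estimates = []
    for model in models:
        if plan == "external":
            model_refs = refs
        else:
            peers = [m for m in models if m is not model]
            if not peers:
                estimates.append(QualityEstimate(model.model_id, None, None, None,
                                                 unscored=True))
                continue
            if plan == "top40":
                # top-n subset chosen among the model's peers, so that a
                # subset covering all peers reproduces all-against-all exactly
                model_refs = select_reference_subset(
                    peers, top_n, lambda m: prescore[m.model_id])
            else:
                model_refs = ReferenceSet(peers, origin="population")
        scores: dict[str, ComponentScore] = {}
        for name in variant.all_components:
            try:
                scores[name] = _compute_component(name, model, model_refs, params,
                                                  adapter_config)
            except (JuryUndefinedError, UndefinedScoreError, AdapterError, ValueError) as exc:
                log.warning("component %s failed for %s: %s", name, model.model_id, exc)

        def mean_of(names: tuple[str, ...]) -> float | None:
            vals = [scores[n].global_value for n in names if n in scores]
            return float(np.clip(np.mean(vals), 0, 1)) if vals else None

        score = mean_of(variant.fold_components)
        qscore = mean_of(variant.interface_components)
        res_vectors = [scores[n].per_residue for n in variant.residue_components
                       if n in scores and scores[n].per_residue is not None]
        n_res = model.total_residues
        res_vectors = [v for v in res_vectors if len(v) == n_res]
        residue_conf = (np.clip(np.mean(res_vectors, axis=0), 0, 1).tolist()
                        if res_vectors else None)

        if score is None and qscore is None and residue_conf is None:
            log.warning("model %s unscored: all components failed", model.model_id)
            estimates.append(QualityEstimate(model.model_id, None, None, None,
                                             unscored=True, components=scores))
        else:
            estimates.append(QualityEstimate(model.model_id, score, qscore,
                                             residue_conf, components=scores))
    if all(e.unscored for e in estimates):
        raise PopulationError("every model in the population is unscored")
    return estimates
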