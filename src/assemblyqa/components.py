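"""The seven individual component scorers feeding the consensus variants.

Four jury (clustering) scores — DockQJury, QSscoreJury, QSscoreOfficialJury
and lDDTOfficialJury — score a model as its mean pairwise similarity to a
reference set (normally the rest of the submitted population).  ModFOLDIA is
a per-residue interface-accuracy clustering score based on the consensus of
cross-chain contact partners; CDA is a contact distance agreement score
against consensus distances; voromqa is an adapter around an external
Voronoi-tessellation scorer with a self-contained internal fallback so the
pipeline runs without external binaries.

ModFOLDIA is realised here as a per-residue Jaccard of cross-chain contact
partner sets averaged over the reference models, and CDA as an lDDT-style
agreement with median consensus Cbeta distances; both are concrete, documented
instantiations of their design (see docs/methods.md).
"""

from __future__ import annotations

import json
import shlex
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .metrics import (
    DEFAULT_PARAMS,
    MetricParams,
    NoInterfaceError,
    UndefinedScoreError,
    build_pair_context,
    compute_dockq,
    compute_oligo_lddt,
    compute_qs,
    model_arrays,
)
from .structures import StructureModel

__all__ = [
    "ComponentScore",
    "ReferenceSet",
    "JuryUndefinedError",
    "AdapterError",
    "JURY_METRICS",
    "jury_score",
    "modfoldia_residue_scores",
    "cda_score",
    "voromqa_score",
]


class JuryUndefinedError(ValueError):
    """Every pairwise comparison of a jury was undefined."""


class AdapterError(RuntimeError):
    """A configured external scoring tool failed."""


@dataclass
class ComponentScore:
    """Result of one component method on one model."""

    method_name: str
    global_value: float
    per_residue: list[float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.global_value <= 1.0:
            raise ValueError(f"{self.method_name}: global value {self.global_value} outside [0,1]")
        if self.per_residue is not None and any(not 0 <= v <= 1 for v in self.per_residue):
            raise ValueError(f"{self.method_name}: per-residue value outside [0,1]")


@dataclass
class ReferenceSet:
    """Models a query is compared against, with their provenance."""

    models: list[StructureModel]
    origin: str = "population"  # population | top40 | external-reference

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("reference set is empty")
        if self.origin not in ("population", "top40", "external-reference"):
            raise ValueError(f"unknown reference origin {self.origin!r}")

    def excluding(self, model: StructureModel) -> "ReferenceSet":
        kept = [m for m in self.models if m is not model]
        if not kept:
            raise ValueError("reference set empty after self-exclusion")
        return ReferenceSet(kept, self.origin)


# jury metric name -> (method_name, pairwise callable)
JURY_METRICS = {
    "dockq": "DockQJury",
    "qs_weighted": "QSscoreJury",
    "qs_official": "QSscoreOfficialJury",
    "oligo_lddt": "lDDTOfficialJury",
}


def _pairwise(metric: str, model: StructureModel, ref: StructureModel,
              params: MetricParams) -> float:
    ctx = build_pair_context(model, ref)
    key = (metric, params)
    if key in ctx.metric_cache:
        hit = ctx.metric_cache[key]
        if isinstance(hit, Exception):
            raise hit
        return hit
    try:
        value = _pairwise_uncached(metric, model, ref, params, ctx)
    except (UndefinedScoreError, NoInterfaceError) as exc:
        ctx.metric_cache[key] = exc
        raise
    ctx.metric_cache[key] = value
    return value


def _pairwise_uncached(metric: str, model: StructureModel, ref: StructureModel,
                       params: MetricParams, ctx) -> float:
    if metric == "dockq":
        return compute_dockq(model, ref, params=params, ctx=ctx)[0]
    if metric == "qs_weighted":
        return compute_qs(model, ref, params=params, dialect="weighted", ctx=ctx)
    if metric == "qs_official":
        return compute_qs(model, ref, params=params, dialect="official", ctx=ctx)
    if metric == "oligo_lddt":
        return compute_oligo_lddt(model, ref, params=params, ctx=ctx)
    raise ValueError(f"unknown jury metric {metric!r}")


def jury_score(model: StructureModel, refs: ReferenceSet, metric: str,
               params: MetricParams = DEFAULT_PARAMS) -> ComponentScore:
    """Mean pairwise similarity of ``model`` to each reference model.

    References play the reference role of directional metrics.  Pairs whose
    score is undefined (e.g. a contactless reference for DockQ) are skipped;
    a jury where every pair is undefined raises :class:`JuryUndefinedError`.
    The scored model itself is never compared against (self-exclusion).
    """
    if metric not in JURY_METRICS:
        raise ValueError(f"unknown jury metric {metric!r}; expected one of {sorted(JURY_METRICS)}")
    values = []
    for ref in refs.models:
        if ref is model:
            continue
        try:
            values.append(_pairwise(metric, model, ref, params))
        except (UndefinedScoreError, NoInterfaceError):
            continue
    if not values:
        raise JuryUndefinedError(f"{JURY_METRICS[metric]}: no defined pairwise comparison")
    # summation order must not depend on how the reference set was assembled
    return ComponentScore(JURY_METRICS[metric],
                          float(np.clip(np.mean(sorted(values)), 0.0, 1.0)))


# ---------------------------------------------------------------------------
# ModFOLDIA: per-residue interface-accuracy clustering score

def _cross_chain_partners(arr, cutoff: float) -> list[set[int]]:
    """Per flat residue index: set of cross-chain partner residue indices."""
    partners: list[set[int]] = [set() for _ in range(arr.n_res)]
    for (i, j) in arr.heavy_residue_contacts(cutoff, inter_chain_only=True):
        partners[i].add(j)
        partners[j].add(i)
    return partners


def modfoldia_residue_scores(model: StructureModel, refs: ReferenceSet,
                             params: MetricParams = DEFAULT_PARAMS) -> ComponentScore:
    """Consensus interface accuracy per residue.

    For residue i the score is the mean, over reference models, of the
    Jaccard overlap between its cross-chain contact-partner set in the model
    and in the reference (partners at ``contact_heavy_cutoff`` heavy-atom
    distance, translated through the chain mapping).  A residue with no
    partners on either side contributes 0 — the score reads as the likelihood
    that the residue belongs to the interface.  The global value is the mean
    over residues that have model-side partners.
    """
    marr = model_arrays(model)
    model_partners = _cross_chain_partners(marr, params.contact_heavy_cutoff)
    per_res = np.zeros(marr.n_res)
    used_refs = 0
    for ref in sorted(refs.models, key=lambda m: m.model_id):
        if ref is model:
            continue
        ctx = build_pair_context(model, ref)
        ref_partners = _cross_chain_partners(ctx.rarr, params.contact_heavy_cutoff)
        used_refs += 1
        for i in range(marr.n_res):
            rj = ctx.ref_res_for_model[i]
            if rj < 0:
                ref_set: set[int] = set()
            else:
                ref_set = {
                    int(ctx.model_res_for_ref[p]) for p in ref_partners[int(rj)]
                    if ctx.model_res_for_ref[p] >= 0
                }
            m_set = model_partners[i]
            union = m_set | ref_set
            if union:
                per_res[i] += len(m_set & ref_set) / len(union)
    if used_refs == 0:
        raise JuryUndefinedError("ModFOLDIA: no usable reference models")
    per_res /= used_refs
    with_contacts = [i for i in range(marr.n_res) if model_partners[i]]
    global_value = float(np.mean(per_res[with_contacts])) if with_contacts else 0.0
    return ComponentScore("ModFOLDIA", float(np.clip(global_value, 0, 1)),
                          per_residue=np.clip(per_res, 0, 1).tolist())


# ---------------------------------------------------------------------------
# CDA: contact distance agreement

CDA_CONSENSUS_FRACTION = 0.5


def cda_score(model: StructureModel, refs: ReferenceSet,
              params: MetricParams = DEFAULT_PARAMS) -> ComponentScore:
    """Agreement of the model's Cbeta distances with consensus reference distances.

    Consensus contacts are residue pairs (intra- or inter-chain) whose Cbeta
    distance is within ``cb_contact_cutoff`` in at least half of the reference
    models; the agreement of the model distance with the median reference
    distance is scored lDDT-style over the four thresholds.  Per-residue
    scores average over the consensus contacts a residue participates in;
    the global value averages over residues with at least one such contact.
    """
    marr = model_arrays(model)
    refs_used = sorted((r for r in refs.models if r is not model),
                       key=lambda m: m.model_id)
    if not refs_used:
        raise JuryUndefinedError("CDA: no usable reference models")

    # per reference: translate its cb contacts into model residue indices
    counts: dict[tuple[int, int], int] = {}
    dists: dict[tuple[int, int], list[float]] = {}
    for ref in refs_used:
        ctx = build_pair_context(model, ref)
        for (ri, rj), d in ctx.rarr.cb_contacts(params.cb_contact_cutoff,
                                                inter_chain_only=False).items():
            mi = ctx.model_res_for_ref[ri]
            mj = ctx.model_res_for_ref[rj]
            if mi < 0 or mj < 0:
                continue
            key = (min(int(mi), int(mj)), max(int(mi), int(mj)))
            counts[key] = counts.get(key, 0) + 1
            dists.setdefault(key, []).append(d)
    n_needed = CDA_CONSENSUS_FRACTION * len(refs_used)
    consensus = {k: float(np.median(v)) for k, v in dists.items()
                 if counts[k] >= n_needed}
    if not consensus:
        raise UndefinedScoreError("CDA: no consensus contacts")

    # model Cbeta coordinates per residue
    cb = marr.cb_atom
    thresholds = params.lddt_thresholds
    per_contact: dict[tuple[int, int], float] = {}
    for (i, j), d_ref in consensus.items():
        if cb[i] < 0 or cb[j] < 0:
            per_contact[(i, j)] = 0.0
            continue
        d_model = float(np.linalg.norm(marr.coords[cb[i]] - marr.coords[cb[j]]))
        diff = abs(d_model - d_ref)
        per_contact[(i, j)] = sum(diff <= t for t in thresholds) / len(thresholds)

    per_res = np.zeros(marr.n_res)
    n_contacts = np.zeros(marr.n_res)
    for (i, j), s in per_contact.items():
        per_res[i] += s
        per_res[j] += s
        n_contacts[i] += 1
        n_contacts[j] += 1
    has = n_contacts > 0
    per_res[has] /= n_contacts[has]
    global_value = float(np.mean(per_res[has])) if has.any() else 0.0
    return ComponentScore("CDA", float(np.clip(global_value, 0, 1)),
                          per_residue=np.clip(per_res, 0, 1).tolist())


# ---------------------------------------------------------------------------
# voromqa adapter with internal fallback

def _voromqa_fallback(model: StructureModel, params: MetricParams) -> ComponentScore:
    arr = model_arrays(model)
    inter = arr.cb_contacts(params.cb_contact_cutoff, inter_chain_only=True)
    c = len(inter)

    # clashes: heavy-atom pairs below clash_cutoff, excluding pairs within a
    # residue and between sequence-adjacent residues of the same chain
    # (covalent neighbours)
    pairs = arr.kdtree.query_pairs(params.clash_cutoff, output_type="ndarray")
    clash_res: set[int] = set()
    x = 0
    if len(pairs):
        ri = arr.atom_res[pairs[:, 0]]
        rj = arr.atom_res[pairs[:, 1]]
        same_chain = arr.res_chain[ri] == arr.res_chain[rj]
        adjacent = same_chain & (np.abs(ri - rj) <= 1)
        mask = (ri != rj) & ~adjacent
        x = int(mask.sum())
        clash_res.update(ri[mask].tolist())
        clash_res.update(rj[mask].tolist())

    global_value = c / (c + 4.0 * x + 10.0)
    contact_res = {i for pair in inter for i in pair}
    per_res = [1.0 if (i in contact_res and i not in clash_res) else 0.0
               for i in range(arr.n_res)]
    return ComponentScore("voromqa", float(np.clip(global_value, 0, 1)), per_res)


def voromqa_score(model: StructureModel, adapter_config: dict | None = None,
                  params: MetricParams = DEFAULT_PARAMS) -> ComponentScore:
    """Voronoi-tessellation single-model score.

    If ``adapter_config`` provides a ``command`` template (with a ``{model}``
    placeholder for a PDB path) the external tool is run and must print a JSON
    object ``{"global": x, "per_residue": [...]}``; values are min-max clamped
    to [0, 1].  Without a configured tool the internal fallback is computed:
    ``C / (C + 4 X + 10)`` with C the inter-chain Cbeta contact count and X the
    heavy-atom clash count, and a binary per-residue interface indicator.
    """
    if adapter_config and adapter_config.get("command"):
        from .structures import write_pdb

        with tempfile.TemporaryDirectory() as tmp:
            pdb = Path(tmp) / f"{model.model_id}.pdb"
            write_pdb(model, pdb)
            cmd = [part.format(model=str(pdb))
                   for part in shlex.split(adapter_config["command"])]
            try:
                proc = subprocess.run(cmd, capture_output=True, text=True, timeout=600)
            except (OSError, subprocess.TimeoutExpired) as exc:
                raise AdapterError(f"voromqa adapter failed to run: {exc}") from exc
            if proc.returncode != 0:
                raise AdapterError(
                    f"voromqa adapter exited {proc.returncode}; stderr: {proc.stderr[:2000]}"
                )
            try:
                payload = json.loads(proc.stdout)
                global_value = float(payload["global"])
                per_res = [float(v) for v in payload.get("per_residue", [])] or None
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise AdapterError(
                    f"voromqa adapter output unparseable: {exc}; stdout: {proc.stdout[:2000]}"
                ) from exc
        global_value = min(max(global_value, 0.0), 1.0)
        if per_res is not None:
            per_res = [min(max(v, 0.0), 1.0) for v in per_res]
        return ComponentScore("voromqa", global_value, per_res)
    return _voromqa_fallback(model, params)
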