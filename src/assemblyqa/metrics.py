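"""Pairwise model-vs-reference similarity scores for protein assemblies.

Implements the superposition-free oligomeric lDDT, the DockQ composite
(fnat / iRMS / LRMS), the QS-score in a weighted and a binary ("official
style") dialect, interface contact similarity (ICS, an F1 over inter-chain
contacts) and interface patch similarity (IPS, a Jaccard over interface
residues), a TM-score with a seeded iterative superposition search, and the
Kabsch least-squares superposition they all share.

All bounded scores live in [0, 1] and equal 1 for a model compared against
itself; iRMS/LRMS are in Angstroms and equal 0 at identity.  oligo-lDDT and
DockQ are directional (the second argument plays the reference role);
QS/ICS/IPS are symmetric.

Derived per-model quantities (KD-trees, contact maps, Cbeta contact weights,
lDDT assessed-pair lists) are cached on the model object, so populations are
scored in roughly O(pairs) gather work rather than O(pairs x atoms^2).
Models are treated as immutable once scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structures import ChainMapping, StructureModel, map_chains, residue_correspondence

__all__ = [
    "MetricParams",
    "ContactMap",
    "PairwiseScoreSet",
    "UndefinedScoreError",
    "NoInterfaceError",
    "DegenerateSuperpositionError",
    "kabsch_superpose",
    "compute_contact_map",
    "compute_oligo_lddt",
    "compute_dockq",
    "dockq_from_terms",
    "compute_qs",
    "compute_ics_ips",
    "compute_tm",
    "compute_pairwise_scores",
    "interface_similarity",
    "model_arrays",
]

ResidueLabel = tuple[str, int]  # (chain_id, residue_number)


class UndefinedScoreError(ValueError):
    """A score has no assessable support (e.g. no reference distance pairs)."""


class NoInterfaceError(UndefinedScoreError):
    """The reference structure has no inter-chain contacts to assess against."""


class DegenerateSuperpositionError(ValueError):
    """Too few points for a meaningful rigid superposition."""


@dataclass(frozen=True)
class MetricParams:
    """Distance cutoffs shared by the pairwise metrics (all in Angstroms)."""

    lddt_thresholds: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
    lddt_radius: float = 15.0
    contact_heavy_cutoff: float = 5.0   # ICS / IPS / fnat heavy-atom contacts
    qs_plateau: float = 5.0             # full weight up to here
    qs_max: float = 12.0                # zero weight beyond here
    clash_cutoff: float = 2.2
    dockq_d1: float = 1.5               # iRMS scaling
    dockq_d2: float = 8.5               # LRMS scaling
    dockq_interface_cutoff: float = 10.0
    cb_contact_cutoff: float = 8.0      # Cbeta contacts (CDA, voromqa fallback)

    def __post_init__(self) -> None:
        if list(self.lddt_thresholds) != sorted(self.lddt_thresholds):
            raise ValueError("lddt_thresholds must be sorted ascending")
        if not self.qs_plateau < self.qs_max:
            raise ValueError("qs_plateau must be below qs_max")
        for name in ("lddt_radius", "contact_heavy_cutoff", "clash_cutoff",
                     "dockq_d1", "dockq_d2", "dockq_interface_cutoff", "cb_contact_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


DEFAULT_PARAMS = MetricParams()


@dataclass
class ContactMap:
    """Inter-chain residue contacts with minimal heavy-atom distances."""

    contacts: dict[tuple[ResidueLabel, ResidueLabel], float]
    cutoff: float

    @property
    def interface_residues(self) -> set[ResidueLabel]:
        out: set[ResidueLabel] = set()
        for a, b in self.contacts:
            out.add(a)
            out.add(b)
        return out

    def __len__(self) -> int:
        return len(self.contacts)


@dataclass
class PairwiseScoreSet:
    """Scores of one directed (model, reference) comparison."""

    oligo_lddt: float | None = None
    dockq: float | None = None
    fnat: float | None = None
    irms: float | None = None
    lrms: float | None = None
    qs: float | None = None
    qs_official: float | None = None
    ics: float | None = None
    ips: float | None = None
    tm: float | None = None


# ---------------------------------------------------------------------------
# cached per-model arrays

_BACKBONE = ("N", "CA", "C", "O")


class ModelArrays:
    """Flat numpy views of a model, built once and cached on the model."""

    def __init__(self, model: StructureModel):
        self.model = model
        res_labels: list[ResidueLabel] = []
        res_chain: list[int] = []
        coords: list[np.ndarray] = []
        atom_res: list[int] = []
        atom_names: list[str] = []
        chain_ids = [c.chain_id for c in model.chains]
        for ci, chain in enumerate(model.chains):
            for res in chain.residues:
                ri = len(res_labels)
                res_labels.append((chain.chain_id, res.number))
                res_chain.append(ci)
                for name, xyz in res.atoms.items():
                    coords.append(xyz)
                    atom_res.append(ri)
                    atom_names.append(name)
        self.chain_ids = chain_ids
        self.sequences = tuple(c.sequence for c in model.chains)
        self.res_labels = res_labels
        self.res_chain = np.asarray(res_chain, dtype=np.int64)
        self.coords = np.asarray(coords, dtype=float)
        self.atom_res = np.asarray(atom_res, dtype=np.int64)
        self.atom_names = atom_names
        self.n_res = len(res_labels)
        self.n_atoms = len(coords)

        self.ca_atom = np.full(self.n_res, -1, dtype=np.int64)
        self.cb_atom = np.full(self.n_res, -1, dtype=np.int64)
        for ai, (ri, name) in enumerate(zip(self.atom_res, atom_names)):
            if name == "CA":
                self.ca_atom[ri] = ai
                if self.cb_atom[ri] < 0:
                    self.cb_atom[ri] = ai  # Gly fallback, overwritten by CB
            elif name == "CB":
                self.cb_atom[ri] = ai

        bb: list[list[int]] = [[] for _ in range(self.n_res)]
        for ai, (ri, name) in enumerate(zip(self.atom_res, atom_names)):
            if name in _BACKBONE:
                bb[int(ri)].append(ai)
        self.backbone_atoms = bb

        # flat residue index -> (chain_id, index within chain)
        self.res_pos: list[tuple[str, int]] = []
        for chain in model.chains:
            for k in range(len(chain.residues)):
                self.res_pos.append((chain.chain_id, k))
        # (chain_id, index within chain) -> flat residue index
        self.flat_of_pos = {pos: i for i, pos in enumerate(self.res_pos)}

        self._cache: dict = {}

    # -- lazy derived data ---------------------------------------------------

    @property
    def kdtree(self) -> cKDTree:
        if "kdtree" not in self._cache:
            self._cache["kdtree"] = cKDTree(self.coords)
        return self._cache["kdtree"]

    def heavy_residue_contacts(self, cutoff: float, inter_chain_only: bool = True
                               ) -> dict[tuple[int, int], float]:
        """Minimal heavy-atom distance per residue pair within ``cutoff``.

        Keys are flat residue index pairs (i < j).
        """
        key = ("heavy_contacts", cutoff, inter_chain_only)
        if key in self._cache:
            return self._cache[key]
        out: dict[tuple[int, int], float] = {}
        if cutoff > 0 and self.n_atoms:
            pairs = self.kdtree.query_pairs(cutoff, output_type="ndarray")
            if len(pairs):
                ri = self.atom_res[pairs[:, 0]]
                rj = self.atom_res[pairs[:, 1]]
                mask = ri != rj
                if inter_chain_only:
                    mask &= self.res_chain[ri] != self.res_chain[rj]
                if mask.any():
                    pi, pj = ri[mask], rj[mask]
                    d = np.linalg.norm(
                        self.coords[pairs[mask, 0]] - self.coords[pairs[mask, 1]], axis=1
                    )
                    lo, hi = np.minimum(pi, pj), np.maximum(pi, pj)
                    for a, b, dist in zip(lo.tolist(), hi.tolist(), d.tolist()):
                        k = (a, b)
                        if k not in out or dist < out[k]:
                            out[k] = dist
        self._cache[key] = out
        return out

    def cb_contacts(self, cutoff: float, inter_chain_only: bool = True
                    ) -> dict[tuple[int, int], float]:
        """Cbeta-Cbeta (Calpha for Gly) distances per residue pair within cutoff."""
        key = ("cb_contacts", cutoff, inter_chain_only)
        if key in self._cache:
            return self._cache[key]
        out: dict[tuple[int, int], float] = {}
        has = self.cb_atom >= 0
        idx = np.where(has)[0]
        if cutoff > 0 and len(idx):
            pts = self.coords[self.cb_atom[idx]]
            tree = cKDTree(pts)
            pairs = tree.query_pairs(cutoff, output_type="ndarray")
            if len(pairs):
                ri = idx[pairs[:, 0]]
                rj = idx[pairs[:, 1]]
                mask = np.ones(len(ri), bool)
                if inter_chain_only:
                    mask = self.res_chain[ri] != self.res_chain[rj]
                d = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
                for a, b, dist in zip(ri[mask].tolist(), rj[mask].tolist(), d[mask].tolist()):
                    out[(min(a, b), max(a, b))] = dist
        self._cache[key] = out
        return out

    def lddt_reference_pairs(self, radius: float) -> tuple[np.ndarray, np.ndarray]:
        """Atom index pairs from different residues within ``radius``, with
        their distances — the assessed set when this model is the reference."""
        key = ("lddt_pairs", radius)
        if key in self._cache:
            return self._cache[key]
        pairs = self.kdtree.query_pairs(radius, output_type="ndarray")
        if len(pairs):
            mask = self.atom_res[pairs[:, 0]] != self.atom_res[pairs[:, 1]]
            pairs = pairs[mask]
            d = np.linalg.norm(self.coords[pairs[:, 0]] - self.coords[pairs[:, 1]], axis=1)
        else:
            pairs = np.empty((0, 2), dtype=np.int64)
            d = np.empty(0)
        self._cache[key] = (pairs, d)
        return pairs, d


def model_arrays(model: StructureModel) -> ModelArrays:
    cache = model.__dict__.setdefault("_cache", {})
    if "arrays" not in cache:
        cache["arrays"] = ModelArrays(model)
    return cache["arrays"]


def _cb_contact_weights(arr: ModelArrays, plateau: float = DEFAULT_PARAMS.qs_plateau,
                        dmax: float = DEFAULT_PARAMS.qs_max
                        ) -> dict[tuple[tuple[str, int], tuple[str, int]], float]:
    """QS contact weights keyed by sorted ((chain, pos-in-chain), ...) pairs."""
    key = ("cb_weights", plateau, dmax)
    if key in arr._cache:
        return arr._cache[key]
    out = {}
    for (i, j), d in arr.cb_contacts(dmax, inter_chain_only=True).items():
        w = 1.0 if d <= plateau else (dmax - d) / (dmax - plateau)
        out[tuple(sorted((arr.res_pos[i], arr.res_pos[j])))] = w
    arr._cache[key] = out
    return out


# ---------------------------------------------------------------------------
# pair context: residue / atom correspondence under a chain mapping

class PairContext:
    """Residue- and atom-level correspondence between model and reference."""

    def __init__(self, model: StructureModel, reference: StructureModel,
                 mapping: ChainMapping):
        self.model = model
        self.reference = reference
        self.mapping = mapping
        ma = model_arrays(model)
        ra = model_arrays(reference)
        self.marr, self.rarr = ma, ra
        self.metric_cache: dict = {}

        # fast path: identical topology under the identity mapping
        if (ma.chain_ids == ra.chain_ids
                and mapping.pairs == [(c, c) for c in ra.chain_ids]
                and ma.sequences == ra.sequences
                and ma.res_labels == ra.res_labels
                and ma.atom_names == ra.atom_names
                and np.array_equal(ma.atom_res, ra.atom_res)):
            self.model_res_for_ref = np.arange(ra.n_res, dtype=np.int64)
            self.ref_res_for_model = np.arange(ma.n_res, dtype=np.int64)
            self.model_atom_for_ref = np.arange(ra.n_atoms, dtype=np.int64)
            return

        self.model_res_for_ref = np.full(ra.n_res, -1, dtype=np.int64)
        self.ref_res_for_model = np.full(ma.n_res, -1, dtype=np.int64)
        for a_id, b_id in mapping.pairs:
            ca, cb = model.chain(a_id), reference.chain(b_id)
            for i, j in residue_correspondence(ca, cb):
                mi = ma.flat_of_pos[(a_id, i)]
                rj = ra.flat_of_pos[(b_id, j)]
                self.model_res_for_ref[rj] = mi
                self.ref_res_for_model[mi] = rj

        # atom correspondence (by name within matched residues)
        self.model_atom_for_ref = np.full(ra.n_atoms, -1, dtype=np.int64)
        model_atom_of = {}
        for ai, (ri, name) in enumerate(zip(ma.atom_res, ma.atom_names)):
            model_atom_of[(int(ri), name)] = ai
        for ai, (rj, name) in enumerate(zip(ra.atom_res, ra.atom_names)):
            mi = self.model_res_for_ref[rj]
            if mi >= 0:
                self.model_atom_for_ref[ai] = model_atom_of.get((int(mi), name), -1)

    # matched Calpha coordinate pairs, mapping order
    def mapped_ca(self) -> tuple[np.ndarray, np.ndarray]:
        key = "_mapped_ca_cache"
        if key in self.__dict__:
            return self.__dict__[key]
        m_idx, r_idx = [], []
        for rj in range(self.rarr.n_res):
            mi = self.model_res_for_ref[rj]
            if mi < 0:
                continue
            ra_ca = self.rarr.ca_atom[rj]
            ma_ca = self.marr.ca_atom[mi]
            if ra_ca >= 0 and ma_ca >= 0:
                m_idx.append(ma_ca)
                r_idx.append(ra_ca)
        out = (self.marr.coords[m_idx], self.rarr.coords[r_idx])
        self.__dict__[key] = out
        return out

    def translate_model_respair(self, i: int, j: int) -> tuple[int, int] | None:
        """Model flat residue pair -> reference flat residue pair, or None."""
        a, b = self.ref_res_for_model[i], self.ref_res_for_model[j]
        if a < 0 or b < 0:
            return None
        return (min(int(a), int(b)), max(int(a), int(b)))


def build_pair_context(model: StructureModel, reference: StructureModel,
                       mapping: ChainMapping | None = None) -> PairContext:
    cache = model.__dict__.setdefault("_cache", {})
    sig = ("ctx", id(reference),
           tuple(mapping.pairs) if mapping is not None else None)
    hit = cache.get(sig)
    # the cache entry keeps the reference object alive so its id stays valid
    if hit is not None and hit.reference is reference:
        return hit
    if mapping is None:
        mapping = map_chains(model, reference)
    ctx = PairContext(model, reference, mapping)
    cache[sig] = ctx
    return ctx


# ---------------------------------------------------------------------------
# Kabsch superposition

def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``coords_b`` onto ``coords_a``.

    Returns ``(rotation, translation, rmsd)`` with ``rotation @ b + translation``
    optimally superposed on ``a``; the rotation is proper (det = +1).
    """
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    if a.shape != b.shape:
        raise ValueError(f"point sets differ in shape: {a.shape} vs {b.shape}")
    if len(a) < 3:
        raise DegenerateSuperpositionError("need at least 3 points")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    h = b0.T @ a0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = ca - rot @ cb
    diff = (b0 @ rot.T) - a0
    rmsd = float(np.sqrt((diff ** 2).sum() / len(a)))
    return rot, trans, rmsd


# ---------------------------------------------------------------------------
# contact map

def compute_contact_map(model: StructureModel, cutoff: float = DEFAULT_PARAMS.contact_heavy_cutoff
                        ) -> ContactMap:
    """All inter-chain residue pairs with minimal heavy-atom distance <= cutoff."""
    arr = model_arrays(model)
    contacts = {}
    for (i, j), d in arr.heavy_residue_contacts(cutoff, inter_chain_only=True).items():
        pair = tuple(sorted((arr.res_labels[i], arr.res_labels[j])))
        contacts[pair] = d
    return ContactMap(contacts=contacts, cutoff=cutoff)


# ---------------------------------------------------------------------------
# oligo-lDDT

def compute_oligo_lddt(model: StructureModel, reference: StructureModel,
                       mapping: ChainMapping | None = None,
                       params: MetricParams = DEFAULT_PARAMS,
                       ctx: PairContext | None = None) -> float:
    """Superposition-free local distance difference test over the whole assembly.

    Assessed pairs are all reference heavy-atom pairs from different residues
    (intra- and inter-chain) within ``lddt_radius``; the score is the mean over
    the four thresholds of the fraction of pairs whose model distance deviates
    from the reference distance by at most the threshold.  Atoms absent from
    the model fail at every threshold.
    """
    if ctx is None:
        ctx = build_pair_context(model, reference, mapping)
    pairs, d_ref = ctx.rarr.lddt_reference_pairs(params.lddt_radius)
    if len(pairs) == 0:
        raise UndefinedScoreError("no assessed distance pairs in reference")
    mi = ctx.model_atom_for_ref[pairs[:, 0]]
    mj = ctx.model_atom_for_ref[pairs[:, 1]]
    mapped = (mi >= 0) & (mj >= 0)
    n = len(pairs)
    if not mapped.any():
        return 0.0
    d_model = np.linalg.norm(
        ctx.marr.coords[mi[mapped]] - ctx.marr.coords[mj[mapped]], axis=1
    )
    diff = np.abs(d_model - d_ref[mapped])
    fracs = [(diff <= t).sum() / n for t in params.lddt_thresholds]
    return float(np.mean(fracs))


# ---------------------------------------------------------------------------
# DockQ

def _ref_contacts(ctx: PairContext, cutoff: float) -> set[tuple[int, int]]:
    return set(ctx.rarr.heavy_residue_contacts(cutoff, inter_chain_only=True))


def _model_contacts_in_ref(ctx: PairContext, cutoff: float) -> set[tuple[int, int]]:
    out = set()
    for (i, j) in ctx.marr.heavy_residue_contacts(cutoff, inter_chain_only=True):
        t = ctx.translate_model_respair(i, j)
        if t is not None:
            out.add(t)
    return out


def _backbone_pairs(ctx: PairContext, ref_res: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Matched backbone coordinates (model, reference) for given ref residues."""
    m_idx, r_idx = [], []
    rarr = ctx.rarr
    for rj in ref_res:
        for ai in rarr.backbone_atoms[int(rj)]:
            mi = ctx.model_atom_for_ref[ai]
            if mi >= 0:
                r_idx.append(ai)
                m_idx.append(int(mi))
    return ctx.marr.coords[m_idx].reshape(-1, 3), rarr.coords[r_idx].reshape(-1, 3)


def compute_dockq(model: StructureModel, reference: StructureModel,
                  mapping: ChainMapping | None = None,
                  params: MetricParams = DEFAULT_PARAMS,
                  ctx: PairContext | None = None
                  ) -> tuple[float, float, float, float]:
    """DockQ composite: returns ``(dockq, fnat, irms, lrms)``.

    fnat is the fraction of reference inter-chain heavy-atom contacts (<= 5 A)
    reproduced by the model; iRMS the backbone RMSD over reference interface
    residues (any heavy atom within 10 A of another chain) after superposing
    on those residues; LRMS the backbone RMSD of the smaller chain of each
    contacting mapped chain pair after superposing on the larger, averaged
    over interfaces.  DockQ = (fnat + 1/(1+(iRMS/d1)^2) + 1/(1+(LRMS/d2)^2))/3.
    """
    if ctx is None:
        ctx = build_pair_context(model, reference, mapping)
    rarr = ctx.rarr
    ref_contacts = _ref_contacts(ctx, params.contact_heavy_cutoff)
    if not ref_contacts:
        raise NoInterfaceError("reference has no inter-chain contacts")
    model_contacts = _model_contacts_in_ref(ctx, params.contact_heavy_cutoff)
    fnat = len(ref_contacts & model_contacts) / len(ref_contacts)

    # interface residues: any heavy atom within dockq_interface_cutoff of another chain
    iface = set()
    for (i, j) in rarr.heavy_residue_contacts(params.dockq_interface_cutoff,
                                              inter_chain_only=True):
        iface.add(i)
        iface.add(j)
    m_pts, r_pts = _backbone_pairs(ctx, np.asarray(sorted(iface), dtype=np.int64))
    if len(m_pts) >= 3:
        _, _, irms = kabsch_superpose(r_pts, m_pts)
    else:
        irms = float("inf")

    # LRMS per contacting mapped chain pair, smaller chain onto larger
    chain_pairs = set()
    for (i, j) in ref_contacts:
        ca, cb = rarr.res_pos[i][0], rarr.res_pos[j][0]
        chain_pairs.add(tuple(sorted((ca, cb))))
    lrms_values = []
    for c1, c2 in sorted(chain_pairs):
        n1 = len(reference.chain(c1).residues)
        n2 = len(reference.chain(c2).residues)
        # receptor = larger chain; ties broken lexicographically
        rec, lig = (c1, c2) if n1 >= n2 else (c2, c1)
        rec_res = np.where([rarr.res_pos[k][0] == rec for k in range(rarr.n_res)])[0]
        lig_res = np.where([rarr.res_pos[k][0] == lig for k in range(rarr.n_res)])[0]
        m_rec, r_rec = _backbone_pairs(ctx, rec_res)
        m_lig, r_lig = _backbone_pairs(ctx, lig_res)
        if len(m_rec) < 3 or len(m_lig) == 0:
            continue
        rot, trans, _ = kabsch_superpose(r_rec, m_rec)
        moved = m_lig @ rot.T + trans
        lrms_values.append(float(np.sqrt(((moved - r_lig) ** 2).sum() / len(r_lig))))
    lrms = float(np.mean(lrms_values)) if lrms_values else float("inf")

    return dockq_from_terms(fnat, irms, lrms, params), fnat, irms, lrms


def dockq_from_terms(fnat: float, irms: float, lrms: float,
                     params: MetricParams = DEFAULT_PARAMS) -> float:
    """DockQ = (fnat + 1/(1+(iRMS/d1)^2) + 1/(1+(LRMS/d2)^2)) / 3."""
    term_i = 1.0 / (1.0 + (irms / params.dockq_d1) ** 2) if np.isfinite(irms) else 0.0
    term_l = 1.0 / (1.0 + (lrms / params.dockq_d2) ** 2) if np.isfinite(lrms) else 0.0
    return (fnat + term_i + term_l) / 3.0


# ---------------------------------------------------------------------------
# QS-score

def compute_qs(model: StructureModel, reference: StructureModel,
               mapping: ChainMapping | None = None,
               params: MetricParams = DEFAULT_PARAMS,
               dialect: str = "weighted",
               ctx: PairContext | None = None) -> float:
    """Quaternary-structure score: conservation of weighted inter-chain contacts.

    Contacts are Cbeta-Cbeta (Calpha for Gly) pairs within ``qs_max``; the
    weight is 1 up to ``qs_plateau`` and falls linearly to 0 at ``qs_max``.
    ``dialect='weighted'`` uses min/max of the ramp weights; ``'official'``
    uses binary weights (a plain Jaccard over the contact sets).
    """
    if dialect not in ("weighted", "official"):
        raise ValueError(f"unknown QS dialect {dialect!r}")
    if ctx is None:
        ctx = build_pair_context(model, reference, mapping)
    marr, rarr = ctx.marr, ctx.rarr

    w_ref = {}
    for (i, j), d in rarr.cb_contacts(params.qs_max, inter_chain_only=True).items():
        w = 1.0 if d <= params.qs_plateau else (params.qs_max - d) / (params.qs_max - params.qs_plateau)
        w_ref[(i, j)] = w
    w_model = {}
    for (i, j), d in marr.cb_contacts(params.qs_max, inter_chain_only=True).items():
        t = ctx.translate_model_respair(i, j)
        w = 1.0 if d <= params.qs_plateau else (params.qs_max - d) / (params.qs_max - params.qs_plateau)
        # contacts among unmapped residues keep a private key: they count in
        # the denominator but can never be shared
        w_model[t if t is not None else ("m", i, j)] = w
    if not w_ref and not w_model:
        raise UndefinedScoreError("no inter-chain contacts in either structure")
    if dialect == "official":
        w_ref = {k: 1.0 for k in w_ref}
        w_model = {k: 1.0 for k in w_model}
    num = den = 0.0
    for k in set(w_ref) | set(w_model):
        a, b = w_model.get(k), w_ref.get(k)
        if a is not None and b is not None:
            num += min(a, b)
            den += max(a, b)
        else:
            den += a if a is not None else b
    return num / den if den else 0.0


# ---------------------------------------------------------------------------
# ICS / IPS

def compute_ics_ips(model_map: ContactMap, reference_map: ContactMap
                    ) -> tuple[float, float]:
    """Interface contact similarity (F1 over contacts) and interface patch
    similarity (Jaccard over interface residues).  Both maps must share one
    residue labelling (translate the model map into reference labels first)."""
    if not reference_map.contacts:
        raise NoInterfaceError("reference contact map is empty")
    m, r = set(model_map.contacts), set(reference_map.contacts)
    tp = len(m & r)
    precision = tp / len(m) if m else 0.0
    recall = tp / len(r)
    ics = (2 * precision * recall / (precision + recall)) if (precision + recall) else 0.0
    mi, ri = model_map.interface_residues, reference_map.interface_residues
    union = mi | ri
    ips = len(mi & ri) / len(union) if union else 0.0
    return ics, ips


def interface_similarity(model: StructureModel, reference: StructureModel,
                         mapping: ChainMapping | None = None,
                         params: MetricParams = DEFAULT_PARAMS,
                         ctx: PairContext | None = None) -> tuple[float, float]:
    """ICS/IPS of model vs reference with the model's contacts translated into
    the reference residue labelling through the chain mapping."""
    if ctx is None:
        ctx = build_pair_context(model, reference, mapping)
    rarr = ctx.rarr
    ref_pairs = _ref_contacts(ctx, params.contact_heavy_cutoff)
    if not ref_pairs:
        raise NoInterfaceError("reference has no inter-chain contacts")
    ref_map = ContactMap(
        {tuple(sorted((rarr.res_labels[i], rarr.res_labels[j]))): 0.0
         for i, j in ref_pairs},
        params.contact_heavy_cutoff,
    )
    model_pairs = _model_contacts_in_ref(ctx, params.contact_heavy_cutoff)
    model_map = ContactMap(
        {tuple(sorted((rarr.res_labels[i], rarr.res_labels[j]))): 0.0
         for i, j in model_pairs},
        params.contact_heavy_cutoff,
    )
    return compute_ics_ips(model_map, ref_map)


# ---------------------------------------------------------------------------
# TM-score

MIN_TM_RESIDUES = 15


def compute_tm(model: StructureModel, reference: StructureModel,
               mapping: ChainMapping | None = None,
               ctx: PairContext | None = None) -> float:
    """TM-score over the mapped Calpha trace of the whole assembly.

    Chains are concatenated in mapping order; d0 follows the standard length
    scaling d0 = 1.24 (L-15)^(1/3) - 1.8 (floored at 0.5 A) with L the
    reference residue count.  The superposition search seeds Kabsch fits from
    sliding windows of decreasing length and iteratively re-fits on the
    residues within the distance cutoff until the selected set is stable; the
    reported score is the best over all seeds.
    """
    if ctx is None:
        ctx = build_pair_context(model, reference, mapping)
    m_ca, r_ca = ctx.mapped_ca()
    n = len(m_ca)
    if n < MIN_TM_RESIDUES:
        raise UndefinedScoreError(f"only {n} mapped residues; need >= {MIN_TM_RESIDUES}")
    l_ref = ctx.rarr.n_res
    d0 = max(1.24 * (l_ref - 15) ** (1.0 / 3.0) - 1.8, 0.5)

    def score_from(rot: np.ndarray, trans: np.ndarray) -> tuple[float, np.ndarray]:
        moved = m_ca @ rot.T + trans
        d = np.linalg.norm(moved - r_ca, axis=1)
        return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_ref), d

    best = 0.0
    window_lengths = []
    w = n
    while w >= 4 and len(window_lengths) < 4:
        window_lengths.append(w)
        w = max(w // 2, 4)
        if window_lengths[-1] == 4:
            break
    # selection cutoffs for the iterative core refinement, widest first
    sel_cutoffs = sorted({max(d0 + 2.5, 4.5), max(d0, 2.0), max(d0 / 2, 1.0)},
                         reverse=True)
    step = 1 if n <= 120 else max(window_lengths[0] // 8, 1)
    for wl in window_lengths:
        for start in range(0, n - wl + 1, step):
            seed = np.arange(start, start + wl)
            for cutoff in sel_cutoffs:
                sel = seed
                prev_sel = None
                for _ in range(20):
                    if len(sel) < 3:
                        break
                    rot, trans, _ = kabsch_superpose(r_ca[sel], m_ca[sel])
                    s, d = score_from(rot, trans)
                    best = max(best, s)
                    new_sel = np.where(d < cutoff)[0]
                    if len(new_sel) < 3:
                        # fall back to the closest residues so the core can shrink
                        new_sel = np.argsort(d)[:4]
                    if prev_sel is not None and np.array_equal(new_sel, prev_sel):
                        break
                    prev_sel, sel = new_sel, new_sel
    return min(best, 1.0)


# ---------------------------------------------------------------------------
# combined

def compute_pairwise_scores(model: StructureModel, reference: StructureModel,
                            mapping: ChainMapping | None = None,
                            params: MetricParams = DEFAULT_PARAMS
                            ) -> PairwiseScoreSet:
    """All pairwise scores of a directed (model, reference) comparison."""
    ctx = build_pair_context(model, reference, mapping)
    out = PairwiseScoreSet()
    out.oligo_lddt = compute_oligo_lddt(model, reference, params=params, ctx=ctx)
    try:
        out.dockq, out.fnat, out.irms, out.lrms = compute_dockq(
            model, reference, params=params, ctx=ctx)
    except NoInterfaceError:
        pass
    try:
        out.qs = compute_qs(model, reference, params=params, dialect="weighted", ctx=ctx)
        out.qs_official = compute_qs(model, reference, params=params, dialect="official", ctx=ctx)
    except UndefinedScoreError:
        pass
    try:
        out.ics, out.ips = interface_similarity(model, reference, params=params, ctx=ctx)
    except NoInterfaceError:
        pass
    try:
        out.tm = compute_tm(model, reference, ctx=ctx)
    except UndefinedScoreError:
        pass
    return out
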