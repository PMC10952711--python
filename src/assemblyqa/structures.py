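"""Reading, normalisation and chain mapping of multimeric structure models.

Model populations submitted for quality assessment are notoriously messy:
chain identifiers may be missing, inconsistent between predictors, or
permuted among sequence-identical chains of a homo-oligomer.  Everything
downstream (contact comparison, lDDT, DockQ, QS-score) presupposes a fixed
residue-level correspondence between two models of the same target, so this
module normalises each file once and solves the chain-assignment problem
explicitly before any score is computed.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from Bio import Align

__all__ = [
    "Residue",
    "Chain",
    "StructureModel",
    "ChainMapping",
    "StructureParseError",
    "EmptyModelError",
    "UnmappableTargetError",
    "read_structure",
    "write_pdb",
    "map_chains",
    "residue_correspondence",
]

# identity level at which two chains are treated as copies of the same entity
SAME_CHAIN_IDENTITY = 0.95
# identity floor below which two chains cannot be mapped to each other
MIN_MAP_IDENTITY = 0.30
# largest sequence-identical group for which the chain permutation is searched
# exhaustively; larger groups fall back to a greedy RMSD assignment
EXHAUSTIVE_GROUP_SIZE = 6

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


class EmptyModelError(ValueError):
    """Raised when a file contains no standard amino-acid residues."""


class UnmappableTargetError(ValueError):
    """Raised when no chain pair between two models reaches the identity floor."""


@dataclass
class Residue:
    """One amino-acid residue: number, 3-letter name and heavy-atom coordinates (Å)."""

    number: int
    name: str
    atoms: dict[str, np.ndarray]

    @property
    def one_letter(self) -> str:
        return _THREE_TO_ONE.get(self.name, "X")


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue]

    @property
    def sequence(self) -> str:
        # chains are treated as immutable once built; cache the join
        seq = self.__dict__.get("_sequence")
        if seq is None or len(seq) != len(self.residues):
            seq = "".join(r.one_letter for r in self.residues)
            self.__dict__["_sequence"] = seq
        return seq

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class StructureModel:
    """A normalised multimeric model: ordered chains of residues of heavy atoms."""

    model_id: str
    target_id: str
    chains: list[Chain]

    @property
    def total_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)

    def validate(self) -> None:
        seen = set()
        for c in self.chains:
            if not c.chain_id:
                raise ValueError("chain with empty identifier")
            if c.chain_id in seen:
                raise ValueError(f"duplicate chain id {c.chain_id!r}")
            seen.add(c.chain_id)
            nums = [r.number for r in c.residues]
            if any(b <= a for a, b in zip(nums, nums[1:])):
                raise ValueError(f"residue numbering not strictly increasing in chain {c.chain_id}")
            for r in c.residues:
                if not r.atoms:
                    raise ValueError(f"residue {c.chain_id}{r.number} has no heavy atoms")
                for name, xyz in r.atoms.items():
                    if not np.all(np.isfinite(xyz)):
                        raise ValueError(f"non-finite coordinates at {c.chain_id}{r.number}:{name}")


@dataclass
class ChainMapping:
    """Injective chain correspondence between two models of the same target."""

    pairs: list[tuple[str, str]]
    unmapped_a: list[str] = field(default_factory=list)
    unmapped_b: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        a_side = [a for a, _ in self.pairs]
        b_side = [b for _, b in self.pairs]
        if len(set(a_side)) != len(a_side) or len(set(b_side)) != len(b_side):
            raise ValueError("chain mapping must be injective on both sides")

    def b_for_a(self, chain_a: str) -> str | None:
        for a, b in self.pairs:
            if a == chain_a:
                return b
        return None


# ---------------------------------------------------------------------------
# reading / writing

_CHAIN_LABELS = string.ascii_uppercase + string.ascii_lowercase + string.digits


def read_structure(path: str | Path, target_id: str = "", model_id: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a normalised :class:`StructureModel`.

    Normalisation drops hetero/solvent records and hydrogens, resolves
    alternate locations to the highest-occupancy conformer, renumbers
    residues strictly increasing within each chain, and replaces missing
    chain identifiers by sequential labels A, B, C... in file order.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise EmptyModelError(f"{path}: no models in file")
    gmodel = st[0]

    chains: list[Chain] = []
    used_labels: set[str] = set()
    for gchain in gmodel:
        residues: list[Residue] = []
        prev_num = None
        for gres in gchain:
            if gres.name not in _THREE_TO_ONE:
                continue  # hetero / solvent / non-standard
            atoms: dict[str, np.ndarray] = {}
            best_occ: dict[str, float] = {}
            for atom in gres:
                if atom.element.is_hydrogen:
                    continue
                occ = atom.occ if atom.occ > 0 else 1.0
                if atom.name not in atoms or occ > best_occ[atom.name]:
                    atoms[atom.name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z], float)
                    best_occ[atom.name] = occ
            if not atoms:
                continue
            if not all(np.all(np.isfinite(v)) for v in atoms.values()):
                raise StructureParseError(
                    f"{path}: non-finite coordinates in residue {gchain.name}/{gres.seqid.num}"
                )
            num = gres.seqid.num
            if prev_num is not None and num <= prev_num:
                num = prev_num + 1
            residues.append(Residue(number=num, name=gres.name, atoms=atoms))
            prev_num = num
        if not residues:
            continue
        label = gchain.name.strip()
        if not label or label in used_labels:
            label = next(l for l in _CHAIN_LABELS if l not in used_labels)
        used_labels.add(label)
        chains.append(Chain(chain_id=label, residues=residues))

    if not chains:
        raise EmptyModelError(f"{path}: no standard protein residues")
    model = StructureModel(
        model_id=model_id if model_id is not None else path.stem,
        target_id=target_id,
        chains=chains,
    )
    model.validate()
    return model


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a normalised model as a minimal PDB file (ATOM/TER/END)."""
    st = gemmi.Structure()
    st.name = model.model_id
    gmodel = gemmi.Model("1")
    for chain in model.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.number, " ")
            for name, xyz in res.atoms.items():
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(name[0])
                atom.pos = gemmi.Position(*map(float, xyz))
                atom.occ = 1.0
                gres.add_atom(atom)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    doc = st.make_pdb_string()
    Path(path).write_text(doc)


# ---------------------------------------------------------------------------
# sequence identity and chain grouping

_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 2.0
_aligner.mismatch_score = -1.0
_aligner.open_gap_score = -5.0
_aligner.extend_gap_score = -0.5


def _align_pair(seq_a: str, seq_b: str) -> list[tuple[int, int]]:
    """Matched (index_a, index_b) positions of a global pairwise alignment."""
    if seq_a == seq_b:
        return [(i, i) for i in range(len(seq_a))]
    aln = _aligner.align(seq_a, seq_b)[0]
    pairs: list[tuple[int, int]] = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        pairs.extend(zip(range(a0, a1), range(b0, b1)))
    return pairs


def sequence_identity(seq_a: str, seq_b: str) -> float:
    """Fraction of identical aligned positions over the longer sequence length."""
    if not seq_a or not seq_b:
        return 0.0
    if seq_a == seq_b:
        return 1.0
    matches = sum(1 for i, j in _align_pair(seq_a, seq_b) if seq_a[i] == seq_b[j])
    return matches / max(len(seq_a), len(seq_b))


def residue_correspondence(chain_a: Chain, chain_b: Chain) -> list[tuple[int, int]]:
    """Residue index pairs (into chain_a.residues / chain_b.residues) from a
    global sequence alignment of the two chains."""
    return _align_pair(chain_a.sequence, chain_b.sequence)


def _identity_groups(model: StructureModel) -> list[list[str]]:
    """Partition chains into groups of mutually near-identical sequence."""
    groups: list[list[str]] = []
    for chain in model.chains:
        for grp in groups:
            rep = model.chain(grp[0])
            if sequence_identity(chain.sequence, rep.sequence) >= SAME_CHAIN_IDENTITY:
                grp.append(chain.chain_id)
                break
        else:
            groups.append([chain.chain_id])
    return groups


# ---------------------------------------------------------------------------
# chain mapping

def _qs_overlap(model_a: StructureModel, model_b: StructureModel,
                pairs: list[tuple[str, str]]) -> float:
    """Shared inter-chain contact weight (the QS-score numerator) under a
    candidate chain assignment.  Used only to rank assignments."""
    from .metrics import _cb_contact_weights, model_arrays  # local import: avoid cycle

    corr: dict[str, str] = dict(pairs)
    wa = _cb_contact_weights(model_arrays(model_a))
    wb = _cb_contact_weights(model_arrays(model_b))

    # translate model-a contacts into model-b residue labels
    index_maps: dict[str, dict[int, int]] = {}
    for a_id, b_id in pairs:
        ca, cb = model_a.chain(a_id), model_b.chain(b_id)
        index_maps[a_id] = dict(residue_correspondence(ca, cb))
    shared = 0.0
    for ((ch1, r1), (ch2, r2)), w in wa.items():
        if ch1 not in corr or ch2 not in corr:
            continue
        m1 = index_maps[ch1].get(r1)
        m2 = index_maps[ch2].get(r2)
        if m1 is None or m2 is None:
            continue
        key = tuple(sorted([(corr[ch1], m1), (corr[ch2], m2)]))
        if key in wb:
            shared += min(w, wb[key])
    return shared


def _chain_rmsd(chain_a: Chain, chain_b: Chain) -> float:
    from .metrics import kabsch_superpose

    corr = residue_correspondence(chain_a, chain_b)
    pa, pb = [], []
    for i, j in corr:
        ra, rb = chain_a.residues[i], chain_b.residues[j]
        if "CA" in ra.atoms and "CA" in rb.atoms:
            pa.append(ra.atoms["CA"])
            pb.append(rb.atoms["CA"])
    if len(pa) < 3:
        return float("inf")
    _, _, rmsd = kabsch_superpose(np.asarray(pa), np.asarray(pb))
    return rmsd


def map_chains(model: StructureModel, reference: StructureModel) -> ChainMapping:
    """Find the chain correspondence between two models of the same target.

    Chains are grouped by sequence identity (mutually >=95% identical chains
    form one group); groups are matched across models by sequence; within a
    matched group the permutation maximising the shared inter-chain contact
    weight is chosen — exhaustively for groups of up to six chains, greedily
    (best per-chain superposition RMSD first) above that.
    """
    if not model.chains or not reference.chains:
        raise ValueError("cannot map empty models")

    groups_a = _identity_groups(model)
    groups_b = _identity_groups(reference)

    # match groups across models by representative identity
    candidates = []
    for ia, ga in enumerate(groups_a):
        for ib, gb in enumerate(groups_b):
            ident = sequence_identity(model.chain(ga[0]).sequence,
                                      reference.chain(gb[0]).sequence)
            if ident >= MIN_MAP_IDENTITY:
                candidates.append((ident, ia, ib))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    group_pairs: list[tuple[int, int]] = []
    for _, ia, ib in candidates:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        group_pairs.append((ia, ib))
    if not group_pairs:
        raise UnmappableTargetError(
            f"no chain pair between {model.model_id} and {reference.model_id} "
            f"reaches {MIN_MAP_IDENTITY:.0%} sequence identity"
        )

    # fixed assignments for singleton-vs-singleton groups; search the rest
    pairs: list[tuple[str, str]] = []
    search_groups: list[tuple[list[str], list[str]]] = []
    for ia, ib in group_pairs:
        ga, gb = groups_a[ia], groups_b[ib]
        if len(ga) == 1 and len(gb) == 1:
            pairs.append((ga[0], gb[0]))
        else:
            search_groups.append((ga, gb))

    for ga, gb in search_groups:
        n = min(len(ga), len(gb))
        if max(len(ga), len(gb)) <= EXHAUSTIVE_GROUP_SIZE:
            # permuting one side against ordered subsets of the other covers
            # every injective assignment exactly once
            best_perm, best_score = None, -1.0
            for a_perm in itertools.permutations(ga, n):
                for b_subset in itertools.combinations(gb, n):
                    cand = list(zip(a_perm, b_subset))
                    score = _qs_overlap(model, reference, pairs + cand)
                    if score > best_score:
                        best_score, best_perm = score, cand
            pairs.extend(best_perm)
        else:
            # greedy: best available pair by per-chain superposition RMSD
            remaining_a, remaining_b = list(ga), list(gb)
            scored = sorted(
                ((_chain_rmsd(model.chain(a), reference.chain(b)), a, b)
                 for a in remaining_a for b in remaining_b),
                key=lambda t: (t[0], t[1], t[2]),
            )
            for _, a, b in scored:
                if a in remaining_a and b in remaining_b:
                    pairs.append((a, b))
                    remaining_a.remove(a)
                    remaining_b.remove(b)
    mapped_a = {a for a, _ in pairs}
    mapped_b = {b for _, b in pairs}
    return ChainMapping(
        pairs=pairs,
        unmapped_a=[c.chain_id for c in model.chains if c.chain_id not in mapped_a],
        unmapped_b=[c.chain_id for c in reference.chains if c.chain_id not in mapped_b],
    )
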