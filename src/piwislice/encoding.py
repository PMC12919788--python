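"""Interaction-centric encoding of guide-target RNA duplexes.

A guide-loaded PIWI complex recognises a target RNA through the geometry of
the guide-target duplex: which guide positions are Watson-Crick paired, which
face a mismatched target nucleotide (and which nucleotide), which guide
positions have no paired target base (deletions, in duplex coordinates), and
where extra target nucleotides bulge out between guide positions (insertions).
This module turns that geometry into the numeric feature blocks consumed by
the regression models:

``G``  guide one-hot, L x 4 (channel order A, C, G, U)
``M``  canonical-match mode, L x 2 (channel 0 = A-U/U-A, channel 1 = C-G/G-C)
``E``  mismatched-target identity, L x 4 (channel order A, C, G, U)
``D``  deletion indicator, length L
``I``  insertion boundary flags, length L + 1 (slot 0 = 5' of g1, slot j =
       immediately 3' of guide position j)

At every position exactly one of match / mismatch / deletion is active, and a
G-U wobble is always encoded as a mismatch with target identity U (or G) --
wobbles are partially stable but never canonical.

Baseline sequence-only encodings (concatenated one-hot, k-mer counts) are also
provided for benchmarking against the interaction-centric representation.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from enum import Enum
import numpy as np

NUCLEOTIDES = "ACGU"
_NUC_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}
COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}

#: per-position width of the full interaction feature vector [G, M, E, D]
POSITION_WIDTH = 11
#: per-position width under the binary match/mismatch simplification [G, match, D]
POSITION_WIDTH_SIMPLE = 6


class PairingError(ValueError):
    """Raised for malformed or inconsistent pairing descriptions."""


def normalize_rna(seq: str) -> str:
    """Uppercase a sequence and convert T to U; validate the alphabet."""
    s = seq.strip().upper().replace("T", "U")
    bad = set(s) - set(NUCLEOTIDES)
    if not s or bad:
        raise PairingError(
            f"invalid RNA sequence {seq!r}: unexpected characters {sorted(bad)}"
            if bad
            else "empty RNA sequence"
        )
    return s


@dataclass(frozen=True)
class GuideSequence:
    """A guide RNA, 5'->3', positions g1..gL."""

    id: str
    nucleotides: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "nucleotides", normalize_rna(self.nucleotides))
        if len(self.nucleotides) < 3:
            raise PairingError(f"guide {self.id!r}: length must be >= 3")

    def __len__(self) -> int:
        return len(self.nucleotides)


class StateKind(Enum):
    MATCH = "M"
    MISMATCH = "X"
    DELETION = "D"


@dataclass(frozen=True)
class PositionState:
    """Duplex state at one guide position.

    ``target`` is the mismatched target nucleotide identity and is set iff
    ``kind`` is MISMATCH.
    """

    kind: StateKind
    target: str | None = None

    def __post_init__(self) -> None:
        if self.kind is StateKind.MISMATCH:
            if self.target not in _NUC_INDEX:
                raise PairingError(f"mismatch state needs a target nucleotide, got {self.target!r}")
        elif self.target is not None:
            raise PairingError(f"{self.kind.name} state carries no target nucleotide")


MATCH = PositionState(StateKind.MATCH)
DELETION = PositionState(StateKind.DELETION)


def mismatch(target_nt: str) -> PositionState:
    return PositionState(StateKind.MISMATCH, target_nt.upper().replace("T", "U"))


@dataclass(frozen=True)
class PairingSpec:
    """Per-position duplex states plus insertion boundary flags.

    ``insertions`` has L+1 binary entries over boundary slots: slot 0 lies 5'
    of g1 and slot j immediately 3' of guide position j. Multiple inserted
    nucleotides at one boundary collapse to a single flag.
    """

    states: tuple[PositionState, ...]
    insertions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        states = tuple(self.states)
        ins = tuple(int(bool(v)) for v in self.insertions) if self.insertions else (0,) * (len(states) + 1)
        if len(states) < 3:
            raise PairingError("pairing spec must cover at least 3 guide positions")
        if len(ins) != len(states) + 1:
            raise PairingError(
                f"insertions must have length L+1={len(states) + 1}, got {len(ins)}"
            )
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "insertions", ins)

    def __len__(self) -> int:
        return len(self.states)

    @property
    def n_mismatches(self) -> int:
        return sum(s.kind is StateKind.MISMATCH for s in self.states)

    @property
    def n_deletions(self) -> int:
        return sum(s.kind is StateKind.DELETION for s in self.states)

    @property
    def n_insertions(self) -> int:
        return sum(self.insertions)

    def mismatch_positions(self) -> list[int]:
        """0-based guide positions carrying a mismatch."""
        return [i for i, s in enumerate(self.states) if s.kind is StateKind.MISMATCH]

    @classmethod
    def all_match(cls, L: int) -> "PairingSpec":
        return cls(states=(MATCH,) * L)


_TOKEN_RE = re.compile(r"^(?:(M|D)(?:\*(\d+))?|X:([ACGUT]))$")


def parse_pairing_string(text: str, L: int) -> PairingSpec:
    """Parse the run-length pairing dialect into a :class:`PairingSpec`.

    Grammar: comma-separated tokens ``M`` / ``M*n`` (matches), ``D`` / ``D*n``
    (deletions), ``X:N`` (mismatch with target nucleotide N); an optional
    suffix ``|ins:j1;j2`` lists 0-based insertion boundary slots in 0..L.
    Example: ``"M*9,X:U,M*16"`` is a single mismatch (target U) at g10 of a
    26-nt guide. The parser is guide-agnostic: whether a mismatch token is
    consistent with the guide (i.e. not secretly a match) is checked at
    encode time.
    """
    if L < 3:
        raise PairingError("L must be >= 3")
    body, _, ins_part = text.strip().partition("|")
    states: list[PositionState] = []
    for token in body.split(","):
        token = token.strip()
        m = _TOKEN_RE.match(token)
        if not m:
            raise PairingError(f"malformed pairing token {token!r} in {text!r}")
        if m.group(3):
            states.append(mismatch(m.group(3)))
        else:
            count = int(m.group(2) or 1)
            state = MATCH if m.group(1) == "M" else DELETION
            states.extend([state] * count)
    if len(states) != L:
        raise PairingError(
            f"pairing string covers {len(states)} positions, expected L={L}: {text!r}"
        )
    insertions = [0] * (L + 1)
    if ins_part:
        if not ins_part.startswith("ins:"):
            raise PairingError(f"malformed insertion suffix {ins_part!r}")
        for slot_txt in ins_part[4:].split(";"):
            try:
                slot = int(slot_txt)
            except ValueError as exc:
                raise PairingError(f"malformed insertion slot {slot_txt!r}") from exc
            if not 0 <= slot <= L:
                raise PairingError(f"insertion slot {slot} outside 0..{L}")
            insertions[slot] = 1
    return PairingSpec(states=tuple(states), insertions=tuple(insertions))


def format_pairing_string(spec: PairingSpec) -> str:
    """Serialize a spec to the canonical dialect; inverse of the parser."""
    tokens: list[str] = []
    for state, group in itertools.groupby(spec.states):
        n = len(list(group))
        if state.kind is StateKind.MISMATCH:
            tokens.extend([f"X:{state.target}"] * n)
        else:
            tokens.append(f"{state.kind.value}*{n}" if n > 1 else state.kind.value)
    out = ",".join(tokens)
    slots = [str(j) for j, v in enumerate(spec.insertions) if v]
    if slots:
        out += "|ins:" + ";".join(slots)
    return out


def spec_from_sequences(guide: GuideSequence, target: str) -> PairingSpec:
    """Build an ungapped spec from the target base paired to each guide position.

    ``target`` lists, for guide positions g1..gL in order, the target
    nucleotide sitting opposite that position (i.e. the paired strand read in
    guide coordinates). A position is MATCH iff that base is the Watson-Crick
    complement of the guide base; anything else (including G-U wobble) is a
    MISMATCH with that base's identity. Indel-containing variants cannot be
    described this way and need an explicit :class:`PairingSpec`.
    """
    t = normalize_rna(target)
    if len(t) != len(guide):
        raise PairingError(
            f"target length {len(t)} != guide length {len(guide)}; provide an "
            "explicit PairingSpec for indel-containing variants"
        )
    states = tuple(
        MATCH if t[i] == COMPLEMENT[g] else mismatch(t[i])
        for i, g in enumerate(guide.nucleotides)
    )
    return PairingSpec(states=states)


@dataclass(frozen=True)
class InteractionEncoding:
    """The numeric feature blocks for one guide-target variant."""

    G: np.ndarray  # (L, 4) guide one-hot
    M: np.ndarray  # (L, 2) canonical match mode
    E: np.ndarray  # (L, 4) mismatched target identity
    D: np.ndarray  # (L,)   deletion indicator
    I: np.ndarray  # (L+1,) insertion boundary flags

    @property
    def L(self) -> int:
        return self.G.shape[0]

    def position_features(self, simple_pairing: bool = False) -> np.ndarray:
        """Per-position feature matrix: (L, 11) = [G, M, E, D] by default, or
        (L, 6) = [G, match, D] with the binary match/mismatch simplification."""
        if simple_pairing:
            match_flag = self.M.sum(axis=1, keepdims=True)
            return np.concatenate([self.G, match_flag, self.D[:, None]], axis=1)
        return np.concatenate([self.G, self.M, self.E, self.D[:, None]], axis=1)


def one_hot(seq: str) -> np.ndarray:
    s = normalize_rna(seq)
    out = np.zeros((len(s), 4))
    out[np.arange(len(s)), [_NUC_INDEX[c] for c in s]] = 1.0
    return out


def encode_interaction(guide: GuideSequence, spec: PairingSpec) -> InteractionEncoding:
    """Encode one (guide, pairing spec) pair into the interaction feature blocks.

    Raises :class:`PairingError` if a MISMATCH state's target nucleotide is the
    guide complement at that position (that would be a match, so the spec is
    inconsistent with this guide).
    """
    L = len(guide)
    if len(spec) != L:
        raise PairingError(f"spec length {len(spec)} != guide length {L}")
    G = one_hot(guide.nucleotides)
    M = np.zeros((L, 2))
    E = np.zeros((L, 4))
    D = np.zeros(L)
    for i, state in enumerate(spec.states):
        g = guide.nucleotides[i]
        if state.kind is StateKind.MATCH:
            M[i, 0 if g in "AU" else 1] = 1.0
        elif state.kind is StateKind.MISMATCH:
            if state.target == COMPLEMENT[g]:
                raise PairingError(
                    f"position g{i + 1}: mismatch target {state.target} is the "
                    f"Watson-Crick complement of guide {g} (that is a match)"
                )
            E[i, _NUC_INDEX[state.target]] = 1.0
        else:
            D[i] = 1.0
    return InteractionEncoding(G=G, M=M, E=E, D=D, I=np.asarray(spec.insertions, dtype=float))


def flatten_interaction(enc: InteractionEncoding, simple_pairing: bool = False) -> np.ndarray:
    """Row-major per-position features followed by the insertion vector.

    Length L*11 + (L+1), or L*6 + (L+1) with ``simple_pairing``.
    """
    return np.concatenate([enc.position_features(simple_pairing).ravel(), enc.I])


def encode_concat_onehot(guide: GuideSequence, target: str) -> np.ndarray:
    """Baseline: guide one-hot concatenated with target one-hot, flattened."""
    blocks = [one_hot(guide.nucleotides).ravel()]
    if target:
        blocks.append(one_hot(target).ravel())
    return np.concatenate(blocks)


def _kmer_counts(seq: str, k: int) -> np.ndarray:
    if len(seq) < k:
        raise PairingError(f"sequence of length {len(seq)} shorter than k={k}")
    counts = np.zeros(4 ** k)
    for i in range(len(seq) - k + 1):
        idx = 0
        for c in seq[i : i + k]:
            idx = idx * 4 + _NUC_INDEX[c]
        counts[idx] += 1.0
    return counts


def encode_kmer(guide: GuideSequence, target: str, k: int = 3) -> np.ndarray:
    """Baseline: overlapping k-mer occurrence counts of guide then target
    (length 2*4^k, k-mers in lexicographic A<C<G<U order)."""
    if k < 1:
        raise PairingError("k must be >= 1")
    return np.concatenate([_kmer_counts(guide.nucleotides, k), _kmer_counts(normalize_rna(target), k)])
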