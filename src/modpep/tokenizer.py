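"""Atom-aware n-gram tokenizer for SMILES strings.

A pretokenizer splits a SMILES string into chemically atomic units (two-letter
halogens, bracket expressions, ring-closure escapes, single characters); a
vocabulary is then learned by counting contiguous runs of those units up to a
character-length limit and keeping the most frequent ones under a total token
budget. Five special tokens occupy the first ids:

====  =======  =================================
id    token    role
====  =======  =================================
0     [PAD]    end-of-sequence padding
1     [UNK]    unknown unit
2     [CLS]    sequence start
3     [SEP]    sequence end
4     [MASK]   masked position
====  =======  =================================
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SPECIAL_TOKENS",
    "PAD_ID",
    "UNK_ID",
    "CLS_ID",
    "SEP_ID",
    "MASK_ID",
    "TokenizationError",
    "TokenizerConfig",
    "Vocabulary",
    "EncodedSequence",
    "DecodedText",
    "pretokenize",
    "train_vocabulary",
    "encode",
    "decode",
    "tokens_per_char",
]

SPECIAL_TOKENS = ("[PAD]", "[UNK]", "[CLS]", "[SEP]", "[MASK]")
PAD_ID, UNK_ID, CLS_ID, SEP_ID, MASK_ID = range(5)


class TokenizationError(ValueError):
    def __init__(self, message: str, offset: int | None = None):
        if offset is not None:
            message = f"{message} (offset {offset})"
        super().__init__(message)
        self.offset = offset


def pretokenize(smiles: str) -> list[str]:
    """Split a SMILES string into atomic units.

    Bracket expressions ``[...]`` and two-digit ring closures ``%nn`` stay
    whole, ``Br``/``Cl`` are single units, everything else is one character.
    The concatenation of the output always equals the input.
    """
    units: list[str] = []
    i, n = 0, len(smiles)
    while i < n:
        ch = smiles[i]
        if ch == "[":
            end = smiles.find("]", i + 1)
            if end < 0:
                raise TokenizationError("unbalanced '[' in SMILES", offset=i)
            units.append(smiles[i : end + 1])
            i = end + 1
        elif ch == "]":
            raise TokenizationError("unmatched ']' in SMILES", offset=i)
        elif ch == "%" and i + 2 < n and smiles[i + 1 : i + 3].isdigit():
            units.append(smiles[i : i + 3])
            i += 3
        elif smiles[i : i + 2] in ("Br", "Cl"):
            units.append(smiles[i : i + 2])
            i += 2
        else:
            units.append(ch)
            i += 1
    return units


@dataclass(frozen=True)
class TokenizerConfig:
    """Vocabulary-learning parameters.

    ``budget`` is the total number of non-special tokens (base units plus
    learned n-grams). Category flags control which kinds of multi-unit runs
    may be learned; single bracket atoms are always part of the base alphabet.
    """

    max_ngram_chars: int = 5
    budget: int = 581
    learn_plain_runs: bool = True
    learn_bracketed: bool = True
    learn_parenthetical: bool = True

    def __post_init__(self):
        if self.max_ngram_chars < 1:
            raise ValueError("max_ngram_chars must be at least 1")
        if self.budget < 1:
            raise ValueError("budget must be positive")


class Vocabulary:
    """Ordered token set with the five special tokens at ids 0-4."""

    def __init__(self, tokens: list[str]):
        if list(tokens[:5]) != list(SPECIAL_TOKENS):
            tokens = list(SPECIAL_TOKENS) + [t for t in tokens if t not in SPECIAL_TOKENS]
        if len(set(tokens)) != len(tokens):
            raise ValueError("duplicate tokens in vocabulary")
        self.tokens: list[str] = list(tokens)
        self.id_of: dict[str, int] = {t: i for i, t in enumerate(self.tokens)}
        # greedy matcher state: only learnable (non-special) tokens, and the
        # maximum number of pretokenizer units any token spans
        self._match: dict[str, int] = {t: i for i, t in enumerate(self.tokens) if i >= 5}
        self.max_span = max((len(pretokenize(t)) for t in self._match), default=1)

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.id_of

    def match_id(self, token: str) -> int | None:
        return self._match.get(token)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for token in self.tokens:
                fh.write(token + "\n")

    @classmethod
    def load(cls, path) -> "Vocabulary":
        with open(path, encoding="utf-8") as fh:
            tokens = [line.rstrip("\n") for line in fh]
        if tokens and tokens[-1] == "":
            tokens.pop()
        if tokens[:5] != list(SPECIAL_TOKENS):
            raise ValueError(f"{path}: first five tokens must be the special tokens")
        return cls(tokens)


def _balanced_parenthetical(units: list[str]) -> bool:
    """True if the run is a single balanced ``(...)`` group."""
    if units[0] != "(" or units[-1] != ")":
        return False
    depth = 0
    for pos, u in enumerate(units):
        if u == "(":
            depth += 1
        elif u == ")":
            depth -= 1
            if depth == 0 and pos != len(units) - 1:
                return False
            if depth < 0:
                return False
    return depth == 0


def _classify_run(units: list[str]) -> str | None:
    """Learnable-category of a multi-unit run, or None if not learnable."""
    has_paren = any(u in "()" for u in units)
    if has_paren:
        return "parenthetical" if _balanced_parenthetical(units) else None
    if any(u.startswith("[") for u in units):
        return "bracketed"
    return "plain"


def train_vocabulary(corpus, config: TokenizerConfig = TokenizerConfig()) -> Vocabulary:
    """Learn a vocabulary from a one-SMILES-per-line corpus file.

    The vocabulary is the five specials, every single unit observed, and the
    most frequent learnable runs (character length <= ``max_ngram_chars``)
    until ``budget`` total non-special tokens are reached. Frequency ties
    break lexicographically, so training is deterministic.
    """
    allowed = {
        "plain": config.learn_plain_runs,
        "bracketed": config.learn_bracketed,
        "parenthetical": config.learn_parenthetical,
    }
    base: set[str] = set()
    counts: Counter = Counter()
    n_lines = 0
    with open(corpus, encoding="utf-8") as fh:
        for line in fh:
            smiles = line.strip()
            if not smiles:
                continue
            n_lines += 1
            units = pretokenize(smiles)
            base.update(units)
            for i in range(len(units)):
                chars = 0
                for j in range(i, len(units)):
                    chars += len(units[j])
                    if chars > config.max_ngram_chars:
                        break
                    if j > i:
                        run = units[i : j + 1]
                        category = _classify_run(run)
                        if category and allowed[category]:
                            counts["".join(run)] += 1
    if n_lines == 0:
        raise ValueError("tokenizer training corpus is empty")

    tokens = sorted(base)
    n_learn = max(config.budget - len(tokens), 0)
    learned = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:n_learn]
    tokens += [t for t, _ in learned]
    return Vocabulary(list(SPECIAL_TOKENS) + tokens)


@dataclass
class EncodedSequence:
    """Token ids framed by [CLS]/[SEP] and padded to a fixed context length."""

    ids: np.ndarray
    attention_flags: np.ndarray
    true_length: int

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.attention_flags = np.asarray(self.attention_flags, dtype=np.int64)


def encode(smiles: str, vocab: Vocabulary, context_len: int = 768) -> EncodedSequence:
    """Greedy longest-match encoding over pretokenizer units."""
    if context_len < 3:
        raise ValueError("context_len must be at least 3")
    units = pretokenize(smiles)
    ids: list[int] = []
    i = 0
    while i < len(units):
        matched = False
        for j in range(min(len(units), i + vocab.max_span), i, -1):
            token_id = vocab.match_id("".join(units[i:j]))
            if token_id is not None:
                ids.append(token_id)
                i = j
                matched = True
                break
        if not matched:
            ids.append(UNK_ID)
            i += 1
    ids = ids[: context_len - 2]  # tail truncation, keep framing
    framed = [CLS_ID] + ids + [SEP_ID]
    true_length = len(framed)
    out = np.full(context_len, PAD_ID, dtype=np.int64)
    out[:true_length] = framed
    flags = np.zeros(context_len, dtype=np.int64)
    flags[:true_length] = 1
    return EncodedSequence(out, flags, true_length)


class DecodedText(str):
    """A decoded SMILES string; ``lossy`` is True if [UNK] positions were hit."""

    lossy: bool = False


def decode(seq: EncodedSequence, vocab: Vocabulary) -> DecodedText:
    """Concatenate non-special tokens; inverse of :func:`encode` when no
    truncation or [UNK] occurred."""
    parts: list[str] = []
    lossy = False
    for token_id in np.asarray(seq.ids).tolist():
        if token_id < 0 or token_id >= len(vocab):
            raise ValueError(f"token id {token_id} out of range for vocabulary")
        if token_id == UNK_ID:
            lossy = True
        elif token_id >= 5:
            parts.append(vocab.tokens[token_id])
    text = DecodedText("".join(parts))
    text.lossy = lossy
    return text


def tokens_per_char(corpus, vocab: Vocabulary | None, context_len: int = 100000) -> float:
    """Mean encoded tokens per character over a corpus; ``vocab=None`` scores
    the single-character baseline."""
    total_tokens = 0
    total_chars = 0
    with open(corpus, encoding="utf-8") as fh:
        for line in fh:
            smiles = line.strip()
            if not smiles:
                continue
            if vocab is None:
                total_tokens += len(smiles)
            else:
                seq = encode(smiles, vocab, context_len=context_len)
                total_tokens += seq.true_length - 2
            total_chars += len(smiles)
    if total_chars == 0:
        raise ValueError("corpus is empty")
    return total_tokens / total_chars
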