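"""Regex SMILES tokenizer with a fixed organic-subset vocabulary.

Tokens cover two-character halogens, bracket atoms (emitted as single
tokens), aromatic atoms, ring-closure digits (incl. %nn), bonds and stereo
marks.  detokenize(tokenize(s)) == s for any SMILES the vocabulary covers.
"""

from __future__ import annotations

import re

__all__ = ["SmilesTokenizer"]

_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|Si|Se|se|@@|%\d{2}"
    r"|[BCNOPSFIbcnops]|[=#\-+\\/()~:.]|\d|@|\*)"
)

_SPECIALS = ("<pad>", "<bos>", "<eos>")

_BASE_VOCAB = (
    "C", "c", "N", "n", "O", "o", "S", "s", "P", "p", "B", "b", "F",
    "Cl", "Br", "I", "Si", "Se", "se",
    "(", ")", "=", "#", "-", "+", "/", "\\", ":", ".", "~", "@", "@@", "*",
    "1", "2", "3", "4", "5", "6", "7", "8", "9", "0",
    "%10", "%11", "%12",
    "[nH]", "[NH]", "[N+]", "[N-]", "[n+]", "[O-]", "[o+]", "[S+]", "[s+]",
    "[C@H]", "[C@@H]", "[C@]", "[C@@]", "[CH]", "[CH2]", "[cH]",
    "[P+]", "[B-]", "[Si]", "[Se]", "[SeH]", "[H]", "[NH2+]", "[NH3+]",
    "[NH+]", "[OH+]", "[S-]", "[C-]", "[CH-]", "[CH2-]", "[N@]", "[N@@]",
)


class SmilesTokenizer:
    def __init__(self, extra_tokens: tuple[str, ...] = ()):
        vocab = list(_SPECIALS) + list(_BASE_VOCAB) + [
            t for t in extra_tokens if t not in _BASE_VOCAB
        ]
        self.tokens = tuple(vocab)
        self.index = {t: i for i, t in enumerate(vocab)}
        self.pad_id = self.index["<pad>"]
        self.bos_id = self.index["<bos>"]
        self.eos_id = self.index["<eos>"]

    @property
    def vocab_size(self) -> int:
        return len(self.tokens)

    def split(self, smiles: str) -> list[str]:
        """Split a SMILES string into surface tokens (no special symbols)."""
        out = []
        pos = 0
        for m in _TOKEN_RE.finditer(smiles):
            if m.start() != pos:
                raise ValueError(
                    f"cannot tokenize SMILES at {smiles[pos:m.start()]!r} "
                    f"in {smiles!r}")
            out.append(m.group(0))
            pos = m.end()
        if pos != len(smiles):
            raise ValueError(
                f"cannot tokenize SMILES at {smiles[pos:]!r} in {smiles!r}")
        return out

    def tokenize(self, smiles: str) -> list[int]:
        """Token ids (without specials).  Raises on out-of-vocabulary."""
        ids = []
        for tok in self.split(smiles):
            if tok not in self.index:
                raise ValueError(f"token {tok!r} is not in the vocabulary")
            ids.append(self.index[tok])
        return ids

    def detokenize(self, ids) -> str:
        parts = []
        for i in ids:
            tok = self.tokens[int(i)]
            if tok in _SPECIALS:
                continue
            parts.append(tok)
        return "".join(parts)

    _ATOM_ORGANIC = frozenset(
        ("B", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I",
         "b", "c", "n", "o", "p", "s", "se", "Si", "Se", "*"))

    @classmethod
    def is_atom_token(cls, tok: str) -> bool:
        """True if the surface token denotes an atom (its position in the
        token stream corresponds to one heavy atom of the parsed molecule;
        [H] never appears for heavy-atom-only SMILES)."""
        return tok in cls._ATOM_ORGANIC or tok.startswith("[")

    def atom_positions(self, tokens: list[str]) -> list[int]:
        """Indices of atom tokens, in order of appearance (matches the atom
        order of a molecule parsed from this SMILES)."""
        return [i for i, t in enumerate(tokens) if self.is_atom_token(t)]

    def encode(self, smiles: str, max_len: int) -> list[int]:
        """<bos> ids <eos>, padded to max_len."""
        ids = [self.bos_id] + self.tokenize(smiles) + [self.eos_id]
        if len(ids) > max_len:
            raise ValueError(f"SMILES longer than max_len={max_len}")
        return ids + [self.pad_id] * (max_len - len(ids))
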