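"""Shared fixtures: in-memory domain strings and a small planted dataset."""

from __future__ import annotations

import random

import pytest

from gcfkit.domain_annotation import DomainHit, DomainString
from gcfkit.synthetic_fixtures import FixtureSpec, generate


def make_string(
    record_id: str,
    tokens: list[str],
    core: list[bool] | None = None,
    subseqs: list[str] | None = None,
) -> DomainString:
    """Build a domain string directly from a token list (one hit per CDS)."""
    core = core if core is not None else [False] * len(tokens)
    hits = []
    for i, tok in enumerate(tokens):
        sub = subseqs[i] if subseqs is not None else tok.ljust(8, "X")
        hits.append(DomainHit(tok, i, 0, len(sub), 50.0, sub))
    return DomainString(record_id, hits, list(core))


def random_string_pair(rng: random.Random, alphabet=None, max_len=12):
    alphabet = alphabet or ["KS", "AT", "KR", "ACP", "TE"]
    def one(rid):
        tokens = [rng.choice(alphabet) for _ in range(rng.randint(1, max_len))]
        core = [rng.random() < 0.3 for _ in tokens]
        return make_string(rid, tokens, core)
    return one("A"), one("B")


@pytest.fixture(scope="session")
def planted(tmp_path_factory):
    """Default planted dataset: 5 families x 8 members, seed 1."""
    out = tmp_path_factory.mktemp("planted")
    spec = FixtureSpec(seed=1)
    return generate(spec, out)
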