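"""Shared fixtures: a hand-derived toy data set and small simulated sets."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pytest

from mirclash.binding import BindingTrainConfig, make_binding_examples, train_binding
from mirclash.io import AgoPeak, ChimericInteraction, MiRNA, UtrRecord
from mirclash.synthetic import SimConfig, simulate_dataset

warnings.filterwarnings("ignore", message=".*ConvergenceWarning.*")

# --- hand-built toy fixture ------------------------------------------------
# Background "CACACA..." contains no U or G, so the only exact seed matches
# are the planted ones, and no background window is within edit distance 1
# of either seed complement.

LET7 = "UGAGGUAGUAGGUUGUAUAGUU"     # seed (nt 2-7) GAGGUA -> site UACCUC
MIRB = "UCCCUGAGACCCUAACUUGUGA"     # seed (nt 2-7) CCCUGA -> site UCAGGG
SITE_LET7 = "UACCUC"
SITE_LET7_ED1 = "UACGUC"            # one substitution
SITE_MIRB = "UCAGGG"

CA = "CACACACACA"                   # 10 nt of seed-free background


def _toy_utrs() -> list[UtrRecord]:
    # T1: let-7 site at [10,16), edit-1 site at [26,32), mirB site at [42,48)
    t1 = CA + SITE_LET7 + CA + SITE_LET7_ED1 + CA + SITE_MIRB + CA
    # T2: let-7 sites at [10,16), [30,36), [46,52); mirB site at [54,60)
    t2 = CA + SITE_LET7 + CA + "CACA" + SITE_LET7 + CA + SITE_LET7 \
        + "CA" + SITE_MIRB + CA
    return [UtrRecord("T1", t1, (len(t1),)), UtrRecord("T2", t2, (len(t2),))]


@dataclass
class ToyFixture:
    mirnas: list
    utrs: list
    interactions: list
    peaks: list
    # hand-derived manifest
    clash_counts: dict
    n_clash_positives: int
    clip_unique: tuple[int, int]      # (positives, negatives)
    clip_all: tuple[int, int]


@pytest.fixture(scope="session")
def toy() -> ToyFixture:
    mirnas = [MiRNA("let-7a", "let-7", LET7), MiRNA("mirB-1", "mirB", MIRB)]
    utrs = _toy_utrs()
    interactions = [
        # passes all three filters (exact seed, supported)
        ChimericInteraction("let-7a", "T1", 8, 18, 2, 1),
        # passes via the edit-distance-1 seed
        ChimericInteraction("let-7a", "T1", 24, 34, 1, 2),
        # wrong miRNA for the site: no seed match within edit 1
        ChimericInteraction("let-7a", "T1", 40, 50, 1, 2),
        # exact seed but no non-chimeric support
        ChimericInteraction("let-7a", "T1", 8, 18, 1, 0),
        # mirB on its own exact site, supported
        ChimericInteraction("mirB-1", "T1", 40, 50, 3, 2),
    ]
    peaks = [
        AgoPeak("T2", 8, 18, 5, "P1"),      # covers the let-7 site at [10,16)
        AgoPeak("T2", 44, 62, 7, "P2"),     # covers let-7 [46,52) AND mirB [54,60)
    ]
    return ToyFixture(
        mirnas=mirnas, utrs=utrs, interactions=interactions, peaks=peaks,
        clash_counts={"input": 5, "known": 5, "in_utr": 5,
                      "seed_match": 4, "supported": 3},
        n_clash_positives=3,
        # unique-family rule: T2@10 positive; T2@30 negative plus the two
        # unbound T1 matches (let-7 @10, mirB @42); the two seeds inside
        # the shared peak P2 are excluded from both classes
        clip_unique=(1, 3),
        clip_all=(3, 3),
    )


# --- small simulated sets (shared; session-scoped for speed) ---------------

@pytest.fixture(scope="session")
def small_sim():
    cfg = SimConfig(rng_seed=7, n_utrs=80, n_clash_candidates=60,
                    n_clip_candidates=120, utr_length_mean=300.0)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def binding_fixture():
    """A trained binding model with its train/test examples (2 tasks)."""
    from mirclash.experiments import binding_sim_config, _truth_binding_examples, _split
    cfg = binding_sim_config(5, n_clip_candidates=160, n_utrs=120, n_tasks=2)
    data = simulate_dataset(cfg)
    examples = _truth_binding_examples(data)
    train, test = _split(examples, 5)
    model = train_binding(train, BindingTrainConfig(rng_seed=5))
    return {"config": cfg, "data": data, "model": model,
            "train": train, "test": test}
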