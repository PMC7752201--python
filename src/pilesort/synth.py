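"""Synthetic sorting studies with planted theme structure.

The generator emulates an open-sorting session: a ground-truth partition of
the quotes into K latent themes is fixed, then each researcher starts from
that partition as their piles and independently perturbs it — at most one
pile split, at most one pile merge, then per-quote moves to a uniformly
chosen different pile.  Every generated study satisfies the open-sorting
protocol (complete coverage, no empty pile, at least two piles).

Defaults mirror a realistic small study: 89 quotes sorted by 4 researchers
around 4 latent themes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .community import GroupingAssignment, canonicalize_assignment, louvain
from .congruence import adjusted_rand_index
from .network import build_cosort_network
from .sortdata import PilesortError, SortingStudy, make_study


class ConfigError(PilesortError, ValueError):
    """Infeasible or inconsistent generator configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for a simulated sorting study.

    ``p_move`` is the per-quote probability (per researcher) that the quote
    is reassigned to a uniformly chosen different pile; ``p_split`` and
    ``p_merge`` are per-researcher probabilities of one random pile
    bisection / one random pile merge.  ``theme_sizes`` is ``"balanced"``
    or an explicit list summing to ``n_quotes``.
    """

    n_quotes: int = 89
    n_researchers: int = 4
    n_themes: int = 4
    theme_sizes: str | tuple[int, ...] = "balanced"
    p_move: float = 0.1
    p_split: float = 0.0
    p_merge: float = 0.0
    seed: int = 0

    def resolved_sizes(self) -> list[int]:
        if self.theme_sizes == "balanced":
            base, extra = divmod(self.n_quotes, self.n_themes)
            return [base + (1 if k < extra else 0) for k in range(self.n_themes)]
        sizes = list(self.theme_sizes)
        if len(sizes) != self.n_themes:
            raise ConfigError(
                f"theme_sizes lists {len(sizes)} sizes for {self.n_themes} themes"
            )
        if any(s < 1 for s in sizes):
            raise ConfigError("every theme must hold at least one quote")
        if sum(sizes) != self.n_quotes:
            raise ConfigError(
                f"theme sizes sum to {sum(sizes)}, expected {self.n_quotes}"
            )
        return sizes

    def validate(self) -> None:
        if self.n_quotes < 4:
            raise ConfigError("need at least 4 quotes")
        if self.n_researchers < 1:
            raise ConfigError("need at least 1 researcher")
        if self.n_themes < 2:
            raise ConfigError("need at least 2 latent themes")
        if self.n_themes > self.n_quotes:
            raise ConfigError("more themes than quotes")
        for name in ("p_move", "p_split", "p_merge"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {p}")
        self.resolved_sizes()


def _perturb_partition(
    piles: list[list[int]], rng: np.random.Generator, config: SyntheticConfig
) -> list[list[int]]:
    piles = [list(p) for p in piles]
    # one optional split: random bisection of a random pile with >= 2 quotes
    if config.p_split > 0 and rng.random() < config.p_split:
        big = [k for k, p in enumerate(piles) if len(p) >= 2]
        if big:
            k = int(rng.choice(big))
            members = list(piles[k])
            rng.shuffle(members)
            cut = int(rng.integers(1, len(members)))
            piles[k] = members[:cut]
            piles.append(members[cut:])
    # one optional merge, rejected if it would leave a single pile
    if config.p_merge > 0 and rng.random() < config.p_merge and len(piles) >= 3:
        k1, k2 = (int(x) for x in rng.choice(len(piles), size=2, replace=False))
        k1, k2 = min(k1, k2), max(k1, k2)
        piles[k1].extend(piles.pop(k2))
    # independent per-quote moves
    quotes = [(k, q) for k, pile in enumerate(piles) for q in pile]
    for k, q in quotes:
        if rng.random() >= config.p_move:
            continue
        src = next(idx for idx, pile in enumerate(piles) if q in pile)
        if len(piles[src]) == 1 and len(piles) <= 2:
            continue  # move would leave fewer than two piles: rejected
        choices = [idx for idx in range(len(piles)) if idx != src]
        dst = int(rng.choice(choices))
        piles[src].remove(q)
        piles[dst].append(q)
        if not piles[src]:
            piles.pop(src)
    return [sorted(p) for p in piles if p]


def generate_study(
    config: SyntheticConfig,
) -> tuple[SortingStudy, GroupingAssignment]:
    """Generate one synthetic study and its planted ground truth.

    Randomness comes from a single seeded stream; each researcher draws
    from an independent sub-stream spawned deterministically from the study
    seed, so regenerating with the same config reproduces the study
    exactly.
    """
    config.validate()
    sizes = config.resolved_sizes()
    truth: dict[int, int] = {}
    q = 1
    for theme_idx, size in enumerate(sizes, start=1):
        for _ in range(size):
            truth[q] = theme_idx
            q += 1
    base_piles: list[list[int]] = [
        [qq for qq, t in truth.items() if t == theme_idx]
        for theme_idx in range(1, config.n_themes + 1)
    ]
    streams = np.random.SeedSequence(config.seed).spawn(config.n_researchers)
    rows: list[tuple[str, int, str]] = []
    for r, stream in enumerate(streams, start=1):
        rng = np.random.default_rng(stream)
        piles = _perturb_partition(base_piles, rng, config)
        for pile_idx, pile in enumerate(piles, start=1):
            for quote in pile:
                rows.append((f"R{r}", quote, str(pile_idx)))
    study = make_study(rows)
    return study, canonicalize_assignment(truth)


def recovery_experiment(
    grid: Sequence[SyntheticConfig],
    replicates: int = 20,
    seed: int = 0,
    resolution: float = 1.0,
) -> pd.DataFrame:
    """Planted-partition recovery sweep over a config grid.

    For each config, ``replicates`` studies are generated (with seeds
    derived deterministically from ``seed``), clustered by Louvain on the
    co-sort network, and scored against the planted truth.  Returns one row
    per config with the mean and standard deviation of the adjusted Rand
    index, the mean number of detected communities, and the fraction of
    replicates recovering exactly the planted community count.
    """
    if replicates < 1:
        raise ConfigError("need at least one replicate")
    rows = []
    for cfg_idx, cfg in enumerate(grid):
        cfg.validate()
        aris = []
        ks = []
        for rep in range(replicates):
            rep_seed = (seed * 1_000_003 + cfg_idx * 10_007 + rep) % (2**31)
            study, truth = generate_study(replace(cfg, seed=rep_seed))
            net = build_cosort_network(study)
            found = louvain(net, seed=rep_seed, resolution=resolution)
            aris.append(adjusted_rand_index(found, truth))
            ks.append(max(found.values()))
        aris_arr = np.array(aris)
        ks_arr = np.array(ks)
        rows.append(
            {
                "n_quotes": cfg.n_quotes,
                "n_researchers": cfg.n_researchers,
                "n_themes": cfg.n_themes,
                "p_move": cfg.p_move,
                "p_split": cfg.p_split,
                "p_merge": cfg.p_merge,
                "mean_ari": float(aris_arr.mean()),
                "sd_ari": float(aris_arr.std(ddof=1)) if replicates > 1 else 0.0,
                "mean_k": float(ks_arr.mean()),
                "exact_k_fraction": float((ks_arr == cfg.n_themes).mean()),
            }
        )
    return pd.DataFrame(rows)
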