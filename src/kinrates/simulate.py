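"""Synthetic study generator.

Produces dated language trees, cognate characters, word forms and corpus
counts with the statistical structure the analysis pipeline assumes: a
posterior-like spread of ultrametric trees, multistate characters born of a
Poisson replacement process (a new cognate class at every replacement), and
corpus frequencies whose log frequency per million is log-linearly coupled
to the true replacement rate with Gaussian noise. Ground truth (true rates,
true classes, latent frequencies) is stored separately from the observable
tables so recovery tests cannot leak.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Sequence, Union

import dendropy
import numpy as np
import pandas as pd

from .types import (
    CorpusCounts,
    KIN_TYPES,
    MultistateCharacter,
    TreeSample,
    ValidationError,
    WordFormTable,
)

log = logging.getLogger(__name__)

YEARS_PER_UNIT = 10_000.0

#: Consonant-heavy alphabet for random word forms.
FORM_ALPHABET = "ptkbdgmnszrlvfwjaeiou"


def _rng(seed: Union[int, np.random.Generator]) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# trees


def simulate_tree(
    n: int, root_age: float = 8700.0, seed: Union[int, np.random.Generator] = 0
) -> dendropy.Tree:
    """Yule (pure-birth) tree on ``n`` leaves, rescaled to be ultrametric with
    root-to-tip depth ``root_age`` years. Leaves are labelled L01, L02, ...
    """
    if n < 2:
        raise ValidationError("need at least 2 leaves")
    rng = _rng(seed)
    tn = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tn)
    tree.is_rooted = True
    root = tree.seed_node
    # forward simulation: start from the root split, split uniform lineages
    # at Exp(i * lambda) waiting times until n tips, then run to the present
    t = 0.0
    active: list[tuple[dendropy.Node, float]] = []
    for _ in range(2):
        c = dendropy.Node()
        root.add_child(c)
        active.append((c, 0.0))
    while len(active) < n:
        t += rng.exponential(1.0 / len(active))
        i = rng.integers(len(active))
        node, birth = active.pop(i)
        node.edge.length = t - birth
        for _ in range(2):
            c = dendropy.Node()
            node.add_child(c)
            active.append((c, t))
    present = t + rng.exponential(1.0 / n)
    width = int(np.ceil(np.log10(n + 1)))
    for node, birth in active:
        node.edge.length = present - birth
    # rescale to the requested depth and attach taxa in a canonical order
    scale = root_age / present
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    for j, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = tn.new_taxon(label=f"L{j + 1:0{width}d}")
    return tree


def jitter_tree_sample(
    tree: dendropy.Tree,
    m: int,
    sd_log: float = 0.1,
    seed: Union[int, np.random.Generator] = 0,
) -> TreeSample:
    """Emulate a posterior tree sample: ``m`` copies of ``tree`` with every
    branch length multiplied by i.i.d. lognormal(0, sd_log) noise.

    ``sd_log=0`` gives identical copies. (The expected inflation factor per
    branch is exp(sd_log^2 / 2).)"""
    if m < 1:
        raise ValidationError("need m >= 1 trees")
    if sd_log < 0:
        raise ValidationError("sd_log must be non-negative")
    rng = _rng(seed)
    out = []
    for _ in range(m):
        t = tree.clone(depth=1)
        for edge in t.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length * float(np.exp(rng.normal(0.0, sd_log)))
        out.append(t)
    return TreeSample(out)


# ---------------------------------------------------------------------------
# characters and forms


def _densify(states: dict, taxa: Sequence[str]) -> dict:
    """Relabel raw class ids to dense 0..k-1 by first appearance in taxon order."""
    relabel: dict = {}
    out = {}
    for t in taxa:
        s = states.get(t)
        if s is None:
            out[t] = None
        else:
            if s not in relabel:
                relabel[s] = len(relabel)
            out[t] = relabel[s]
    return out


def simulate_character(
    tree: dendropy.Tree,
    rate_per10kyr: float,
    mode: str = "infinite_alleles",
    seed: Union[int, np.random.Generator] = 0,
    pi: Optional[np.ndarray] = None,
    meaning: str = "sim",
) -> tuple[MultistateCharacter, int]:
    """Evolve one multistate cognate character down a dated tree.

    Events arrive as a Poisson process along branches with intensity matched
    so the *observable* replacement rate equals ``rate_per10kyr``:

    - ``infinite_alleles`` (default): every event creates a brand-new class,
      so the event intensity is the rate itself. This mirrors how new
      cognate classes arise historically.
    - ``f81``: events redraw the state from ``pi`` (possibly landing on the
      same state), so the intensity is rate / (1 - sum pi^2). This makes the
      rate estimator exactly well-specified.

    Returns the character (states dense by first appearance over the sorted
    taxon order) and the total number of events placed on the tree."""
    if rate_per10kyr < 0:
        raise ValidationError("rate must be non-negative")
    rng = _rng(seed)
    if mode == "infinite_alleles":
        intensity = rate_per10kyr
    elif mode == "f81":
        if pi is None:
            raise ValidationError("f81 mode requires pi")
        pi = np.asarray(pi, dtype=float)
        norm = 1.0 - float(np.sum(pi**2))
        if norm <= 0:
            raise ValidationError("degenerate pi: no observable change possible")
        intensity = rate_per10kyr / norm
    else:
        raise ValidationError(f"unknown mode {mode!r}")

    counter = [0]
    if mode == "f81":
        root_state = int(rng.choice(len(pi), p=pi))
    else:
        root_state = 0
        counter[0] = 1
    state_at: dict[int, int] = {id(tree.seed_node): root_state}
    n_events = 0
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        length_units = (node.edge.length or 0.0) / YEARS_PER_UNIT
        s = state_at[id(node.parent_node)]
        k_ev = int(rng.poisson(intensity * length_units))
        n_events += k_ev
        for _ in range(k_ev):
            if mode == "infinite_alleles":
                s = counter[0]
                counter[0] += 1
            else:
                s = int(rng.choice(len(pi), p=pi))
        state_at[id(node)] = s
    raw = {leaf.taxon.label: state_at[id(leaf)] for leaf in tree.leaf_node_iter()}
    states = _densify(raw, sorted(raw))
    return MultistateCharacter(meaning=meaning, states=states), n_events


def _random_form(rng: np.random.Generator, alphabet: str) -> str:
    length = int(rng.integers(4, 9))
    return "".join(rng.choice(list(alphabet), size=length))


def _drift(form: str, n_edits: int, rng: np.random.Generator, alphabet: str) -> str:
    chars = list(form)
    for _ in range(n_edits):
        i = int(rng.integers(len(chars)))
        chars[i] = str(rng.choice(list(alphabet)))
    return "".join(chars)


def simulate_form_evolution(
    tree: dendropy.Tree,
    rate_per10kyr: float,
    alphabet: str = FORM_ALPHABET,
    drift_prob: float = 0.02,
    seed: Union[int, np.random.Generator] = 0,
    meaning: str = "sim",
) -> tuple[dict[str, str], MultistateCharacter]:
    """Evolve word forms down the tree: replacement events (Poisson, rate
    ``rate_per10kyr``) draw an entirely new random form of length 4-8;
    between events, forms accumulate single-segment substitutions at
    ``drift_prob`` per segment per 1,000 years.

    Returns (tip forms by taxon, true-class character)."""
    if len(set(alphabet)) < 5:
        raise ValidationError("alphabet needs at least 5 distinct symbols")
    rng = _rng(seed)
    counter = [1]
    root_form = _random_form(rng, alphabet)
    form_at: dict[int, str] = {id(tree.seed_node): root_form}
    class_at: dict[int, int] = {id(tree.seed_node): 0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        length_years = node.edge.length or 0.0
        form = form_at[id(node.parent_node)]
        cls = class_at[id(node.parent_node)]
        units = length_years / YEARS_PER_UNIT
        k_ev = int(rng.poisson(rate_per10kyr * units))
        # split the branch into k_ev+1 stretches; drift acts per stretch
        cuts = np.sort(rng.uniform(0.0, length_years, size=k_ev)) if k_ev else np.array([])
        bounds = np.concatenate([[0.0], cuts, [length_years]])
        for seg_i in range(k_ev + 1):
            span = bounds[seg_i + 1] - bounds[seg_i]
            if seg_i > 0:  # a replacement happened at the stretch start
                form = _random_form(rng, alphabet)
                cls = counter[0]
                counter[0] += 1
            mean_edits = drift_prob * len(form) * span / 1000.0
            n_edits = int(rng.poisson(mean_edits))
            if n_edits:
                form = _drift(form, n_edits, rng, alphabet)
        form_at[id(node)] = form
        class_at[id(node)] = cls
    tips = {leaf.taxon.label: form_at[id(leaf)] for leaf in tree.leaf_node_iter()}
    raw = {leaf.taxon.label: class_at[id(leaf)] for leaf in tree.leaf_node_iter()}
    char = MultistateCharacter(meaning=meaning, states=_densify(raw, sorted(raw)))
    return tips, char


# ---------------------------------------------------------------------------
# frequencies


@dataclasses.dataclass(frozen=True)
class FrequencyCoupling:
    """Log-linear coupling of latent usage frequency to the true rate:
    log fpm_m = a + b log R*_m + Normal(0, sigma)."""

    a: float = 3.0
    b: float = -0.58
    sigma: float = 0.3

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValidationError("sigma must be non-negative")


def default_corpora(
    languages: Sequence[str],
    n_corpora: int = 34,
    n_corpus_languages: int = 21,
    seed: Union[int, np.random.Generator] = 0,
) -> pd.DataFrame:
    """Corpora specification mirroring the study layout: ``n_corpora``
    corpora across ``n_corpus_languages`` languages in three types (spoken,
    written, web), token sizes log-uniform between 1M and 100M."""
    rng = _rng(seed)
    langs = list(languages)[:n_corpus_languages]
    if not langs:
        raise ValidationError("no languages for corpora")
    types = ["spoken", "written", "web"]
    rows = []
    for i in range(n_corpora):
        rows.append(
            {
                "corpus_id": f"corp{i + 1:02d}",
                "language": langs[i % len(langs)],
                "corpus_type": types[i % 3],
                "corpus_size": int(10 ** rng.uniform(6, 8)),
            }
        )
    return pd.DataFrame(rows)


def simulate_frequencies(
    true_rates: dict[str, float],
    forms: dict[tuple[str, str], str],
    corpora: pd.DataFrame,
    coupling: FrequencyCoupling = FrequencyCoupling(),
    seed: Union[int, np.random.Generator] = 0,
) -> tuple[CorpusCounts, pd.DataFrame]:
    """Generate corpus counts whose latent frequencies track the true rates.

    Per meaning m: latent log fpm = a + b log R*_m + Normal(0, sigma); per
    (corpus, language) the observed count is Poisson(fpm * size / 1e6) for
    the language's word form. ``forms`` maps (language, meaning) -> form.

    Returns the observable counts and the latent truth table (meaning,
    true_rate, latent_fpm)."""
    rng = _rng(seed)
    meanings = sorted(true_rates)
    latent = {}
    for m in meanings:
        r = true_rates[m]
        if r <= 0:
            raise ValidationError(f"true rate for {m!r} must be positive")
        latent[m] = float(
            np.exp(coupling.a + coupling.b * np.log(r) + rng.normal(0.0, coupling.sigma))
        )
    rows = []
    for corp in corpora.itertuples(index=False):
        for m in meanings:
            form = forms.get((corp.language, m))
            if form is None:
                continue
            lam = latent[m] * corp.corpus_size / 1e6
            count = int(rng.poisson(lam))
            rows.append(
                {
                    "language": corp.language,
                    "form": form,
                    "meaning": m,
                    "corpus_id": corp.corpus_id,
                    "corpus_type": corp.corpus_type,
                    "count": min(count, int(corp.corpus_size)),
                    "corpus_size": int(corp.corpus_size),
                }
            )
    truth = pd.DataFrame(
        {
            "meaning": meanings,
            "true_rate": [true_rates[m] for m in meanings],
            "latent_fpm": [latent[m] for m in meanings],
        }
    )
    return CorpusCounts(pd.DataFrame(rows)), truth


# ---------------------------------------------------------------------------
# regression-table generator (for estimator-recovery studies)


def simulate_regression_table(
    n_languages: int = 20,
    n_meanings: int = 100,
    beta0: float = 0.5,
    beta_freq: float = -0.58,
    beta_class: float = 0.2,
    beta_int: float = 0.18,
    sigma: float = 0.3,
    language_sd: float = 0.2,
    seed: Union[int, np.random.Generator] = 0,
) -> pd.DataFrame:
    """Draw a regression table directly from the mixed model.

    log mean_rate = beta0 + beta_freq*clfpm + beta_class*[swadesh]
                    + beta_int*clfpm*[swadesh] + u_language + Normal(0, sigma),
    with clfpm ~ N(0, 1), u_language ~ N(0, language_sd), and the first half
    of the meanings kin, the rest swadesh. One row per language x meaning."""
    rng = _rng(seed)
    langs = [f"L{i + 1:02d}" for i in range(n_languages)]
    u = dict(zip(langs, rng.normal(0.0, language_sd, n_languages)))
    rows = []
    for j in range(n_meanings):
        cls = "kin" if j < n_meanings // 2 else "swadesh"
        for lang in langs:
            clfpm = float(rng.normal())
            sw = 1.0 if cls == "swadesh" else 0.0
            y = (
                beta0
                + beta_freq * clfpm
                + beta_class * sw
                + beta_int * clfpm * sw
                + u[lang]
                + rng.normal(0.0, sigma)
            )
            rows.append(
                {
                    "language": lang,
                    "meaning": f"m{j + 1:03d}",
                    "lexical_class": cls,
                    "clfpm": clfpm,
                    "mean_rate": float(np.exp(y)),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the full study fixture


@dataclasses.dataclass
class SimulationConfig:
    """Study conditions for the synthetic fixture.

    Defaults mirror the real study's shape: 47 languages on trees rooted at
    8,700 years, a 1,000-tree posterior-like sample, 10 kin meanings plus 190
    open-class (swadesh) meanings, corpus counts from 34 corpora in 21
    languages, and a frequency-rate coupling with slope -0.58. True rates are
    log-spaced: kin meanings span 0.3-3 and swadesh meanings 0.8-10 events
    per 10 kyr, so kin meanings are on average slower (hence, under the
    negative coupling, more frequent)."""

    n_languages: int = 47
    root_age_years: float = 8700.0
    n_trees: int = 1000
    tree_sd_log: float = 0.1
    n_swadesh: int = 190
    kin_rate_range: tuple[float, float] = (0.3, 3.0)
    swadesh_rate_range: tuple[float, float] = (0.8, 10.0)
    coupling: FrequencyCoupling = dataclasses.field(default_factory=FrequencyCoupling)
    n_corpora: int = 34
    n_corpus_languages: int = 21
    drift_prob: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.kin_rate_range, self.swadesh_rate_range):
            if not (0 < lo <= hi):
                raise ValidationError("rate ranges must be positive and ordered")
        if self.n_languages < 2 or self.n_trees < 1:
            raise ValidationError("need >= 2 languages and >= 1 tree")

    def true_rates(self) -> dict[str, float]:
        """Deterministic per-meaning true rates (log-spaced within class)."""
        out = {}
        lo, hi = self.kin_rate_range
        for m, r in zip(KIN_TYPES, np.geomspace(lo, hi, len(KIN_TYPES))):
            out[m] = float(r)
        lo, hi = self.swadesh_rate_range
        for j, r in enumerate(np.geomspace(lo, hi, self.n_swadesh)):
            out[f"sw{j + 1:03d}"] = float(r)
        return out


@dataclasses.dataclass
class SyntheticStudy:
    """One synthetic study: observables plus separately held ground truth."""

    config: SimulationConfig
    trees: TreeSample
    wordlist: WordFormTable
    true_characters: dict[str, MultistateCharacter]
    counts: CorpusCounts
    truth: pd.DataFrame  # meaning, true_rate, latent_fpm


def make_study_fixture(
    config: SimulationConfig, seed: Optional[int] = None
) -> SyntheticStudy:
    """Generate an end-to-end consistent synthetic study (deterministic per seed)."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    master = simulate_tree(config.n_languages, config.root_age_years, rng)
    trees = jitter_tree_sample(master, config.n_trees, config.tree_sd_log, rng)
    rates = config.true_rates()
    rows = []
    chars: dict[str, MultistateCharacter] = {}
    forms: dict[tuple[str, str], str] = {}
    for m in sorted(rates):
        tip_forms, char = simulate_form_evolution(
            master, rates[m], drift_prob=config.drift_prob, seed=rng, meaning=m
        )
        chars[m] = char
        cls = "kin" if m in KIN_TYPES else "swadesh"
        for lang, form in sorted(tip_forms.items()):
            forms[(lang, m)] = form
            rows.append(
                {
                    "language": lang,
                    "meaning": m,
                    "form": form,
                    "transcription": form,
                    "lexical_class": cls,
                }
            )
    wordlist = WordFormTable(pd.DataFrame(rows))
    corpora = default_corpora(
        sorted({l for (l, _m) in forms}),
        config.n_corpora,
        config.n_corpus_languages,
        rng,
    )
    counts, truth = simulate_frequencies(rates, forms, corpora, config.coupling, rng)
    return SyntheticStudy(
        config=config,
        trees=trees,
        wordlist=wordlist,
        true_characters=chars,
        counts=counts,
        truth=truth,
    )


def write_study(study: SyntheticStudy, outdir: Union[str, Path]) -> dict:
    """Write all study files in the standard formats plus a manifest.

    Observable files (word list, trees, counts) never contain ground truth;
    truth goes to its own file. Returns the manifest dict."""
    from . import io as kio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}
    kio.write_wordlist(study.wordlist, outdir / "wordlist.csv")
    files["wordlist"] = "wordlist.csv"
    kio.write_tree_sample(study.trees, outdir / "trees.nex", format="nexus")
    files["trees"] = "trees.nex"
    kio.write_frequency_table(study.counts, outdir / "frequencies.csv")
    files["frequencies"] = "frequencies.csv"
    study.truth.to_csv(outdir / "truth.csv", index=False)
    files["truth"] = "truth.csv"
    # true classes as CSV: unlike the NEXUS matrix there is no 36-state cap,
    # and fast meanings on many languages can exceed it
    class_rows = [
        {"meaning": m, "language": lang, "true_class": s}
        for m in sorted(study.true_characters)
        for lang, s in sorted(study.true_characters[m].states.items())
    ]
    pd.DataFrame(class_rows).to_csv(outdir / "true_classes.csv", index=False)
    files["true_classes"] = "true_classes.csv"
    cfg = dataclasses.asdict(study.config)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    manifest = {"seed": study.config.seed, "config": cfg, "config_hash": cfg_hash,
                "files": files}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
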