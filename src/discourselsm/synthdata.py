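"""Synthetic cohorts for end-to-end testing of the discourse pipeline.

The generator emulates the statistical structure the analysis assumes,
not linguistic or anatomical realism: a Rasch (one-parameter logistic)
item-production process with spread difficulties; transcripts whose
correct-information-unit counts exceed the checklist score (extra
relevant words, function words); fillers, immediate repetitions and
inflected surface forms to exercise the scoring rules; connected random
lesion blobs on a desk-scale grid whose load in a designated critical
region depresses latent ability; and a tract atlas plus streamline
template for the disconnection and tract-load analyses.

Ability model: theta_i = -effect_beta * (critical-region lesion load)_i
+ eps_i with eps ~ N(0, noise_sd).  theta is kept on a fixed scale (not
cohort-standardized) so the mean checklist score is monotone in
effect_beta; with effect_beta = 0 and the default noise_sd = 1, theta is
exactly standard normal and shares the item-difficulty scale.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .lesionmap import (CohortLesions, LesionVolume, StreamlineSet, TractAtlas,
                        save_streamlines_json, save_tract_atlas_json,
                        save_volume_nifti)
from .transcripts import (Checklist, ChecklistItem, Token, Transcript,
                          normalize_token, write_checklist,
                          write_transcript_tsv)

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "generate_checklist",
    "generate_cohort",
    "generate_streamlines",
    "write_cohort",
]

# Cookie-theft-flavoured vocabulary. Nouns/verbs with curated synonym sets;
# synonym sets are disjoint from each other and from every lemma.
_NOUNS = [
    "cookie", "jar", "stool", "sink", "water", "dish", "mother", "boy",
    "girl", "window", "curtain", "kitchen", "cupboard", "child", "plate",
]
_VERBS = ["steal", "fall", "wash", "dry", "reach", "take", "overflow"]
_SYNONYMS = {
    "cookie": ["biscuit"], "steal": ["swipe", "pinch"], "mother": ["mom", "mum"],
    "fall": ["topple"], "stool": ["footstool"], "sink": ["basin"],
    "boy": ["lad"], "girl": ["lass"], "curtain": ["drape"],
    "cupboard": ["cabinet"], "take": ["grab"], "wash": ["rinse"],
    "child": ["kid"], "jar": ["pot"], "dish": ["bowl"],
}
_FUNCTION_WORDS = ["the", "a", "is", "and", "he", "she", "it", "on", "in",
                   "to", "there", "was", "while", "then"]
_FILLERS = ["um", "uh", "er"]
_EXTRA_RELEVANT = [
    "tap", "counter", "floor", "apron", "cup", "towel", "garden", "outside",
    "shelf", "faucet", "puddle", "mess", "chair", "foot", "hand", "arm",
    "ladder", "door", "lawn", "path", "spill", "slip", "tip", "stretch",
    "grasp", "lean", "drip", "splash",
]
_OFF_TOPIC = ["weather", "lunch", "television", "yesterday", "holiday", "football"]
_TRACT_NAMES = ["FAT", "AF", "SLF1", "SLF2", "SLF3", "IFOF", "ILF", "UF"]


@dataclass(frozen=True)
class SimulationConfig:
    n_participants: int = 76
    n_items: int = 22
    grid_shape: tuple = (32, 32, 32)
    voxel_size_mm: float = 2.0
    critical_region: tuple | None = None  # voxel index triples; default: generated blob
    effect_beta: float = 2.0
    noise_sd: float = 1.0
    filler_rate: float = 0.15
    repetition_rate: float = 0.08
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 0:
            raise ValueError("n_participants must be >= 0")
        if self.n_items < 1:
            raise ValueError("n_items must be >= 1")
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        if self.voxel_size_mm <= 0 or self.noise_sd <= 0:
            raise ValueError("voxel_size_mm and noise_sd must be positive")
        for name in ("filler_rate", "repetition_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability")
        if self.critical_region is not None:
            region = tuple(tuple(int(c) for c in v) for v in self.critical_region)
            shape = self.grid_shape
            for v in region:
                if any(c < 0 or c >= s for c, s in zip(v, shape)):
                    raise ValueError("critical_region voxel outside grid")
            if len(region) == 0 and self.effect_beta != 0.0:
                raise ValueError("empty critical_region with nonzero effect_beta")
            object.__setattr__(self, "critical_region", region)


@dataclass(frozen=True)
class SyntheticCohort:
    checklist: Checklist
    transcripts: tuple
    lesions: CohortLesions
    abilities: np.ndarray
    tract_atlas: TractAtlas
    streamlines: StreamlineSet
    true_difficulties: np.ndarray
    critical_region: tuple
    config: SimulationConfig
    aphasia_type: tuple = ()
    severity: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self):
        n = len(self.transcripts)
        if len(self.lesions) != n or len(self.abilities) != n:
            raise ValueError("cohort field lengths are inconsistent")
        if not np.all(np.isfinite(self.abilities)):
            raise ValueError("abilities must be finite")


def generate_checklist(n_items: int, seed: int = 0) -> Checklist:
    """A checklist of target items with standard-normal difficulties,
    0-3 synonyms each, and psycholinguistic covariates spanning
    realistic ranges (length 2-7 phonemes, log frequency ~0.8-4.6,
    imageability ~230-640, nouns:verbs roughly 2:1)."""
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    rng = np.random.default_rng(seed)
    lemmas = []
    classes = []
    n_verbs = max(1, round(n_items * 7 / 22)) if n_items > 1 else 0
    pool_v, pool_n = list(_VERBS), list(_NOUNS)
    for i in range(n_items):
        want_verb = i < n_verbs
        pool = pool_v if (want_verb and pool_v) else pool_n
        if not pool:  # out of curated words: synthesize neutral lemmas
            lemmas.append(f"item{i:02d}")
            classes.append("noun")
            continue
        idx = int(rng.integers(len(pool)))
        lemmas.append(pool.pop(idx))
        classes.append("verb" if pool is pool_v else "noun")
    items = []
    for i, (lemma, wclass) in enumerate(zip(lemmas, classes)):
        syn_pool = _SYNONYMS.get(lemma, [])
        n_syn = int(rng.integers(0, min(3, len(syn_pool)) + 1))
        syns = frozenset(rng.choice(syn_pool, size=n_syn, replace=False)) if n_syn else frozenset()
        items.append(ChecklistItem(
            item_id=f"w{i:02d}", lemma=lemma, synonyms=syns, word_class=wclass,
            length_phonemes=int(rng.integers(2, 8)),
            frequency=float(np.round(rng.uniform(0.77, 4.56), 3)),
            imageability=float(np.round(rng.uniform(230.0, 638.0), 1)),
        ))
    return Checklist(items=tuple(items), stimulus_name="synthetic-picture")


def item_difficulties(checklist: Checklist, seed: int = 0) -> np.ndarray:
    """Standard-normal item difficulties, deterministic in (checklist size, seed)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 911]))
    return rng.standard_normal(len(checklist))


def _grow_blob(rng, shape, seed_voxel, target_size):
    """Connected blob by iterative random 6-neighbour accretion."""
    shape = tuple(shape)
    inside = {tuple(seed_voxel)}
    frontier = []
    def push_neighbours(v):
        for axis in range(3):
            for d in (-1, 1):
                nb = list(v)
                nb[axis] += d
                nb = tuple(nb)
                if all(0 <= c < s for c, s in zip(nb, shape)) and nb not in inside:
                    frontier.append(nb)
    push_neighbours(tuple(seed_voxel))
    while len(inside) < target_size and frontier:
        idx = int(rng.integers(len(frontier)))
        vox = frontier.pop(idx)
        if vox in inside:
            continue
        inside.add(vox)
        push_neighbours(vox)
    return np.array(sorted(inside), dtype=int)


def _default_critical_region(rng, shape):
    center = np.array([int(s * 0.35) for s in shape])
    return _grow_blob(rng, shape, center, 20)


def _inflect(lemma: str, rng) -> str:
    """Random inflected surface whose normalization provably recovers the
    lemma (candidates that fail round-trip fall back to the bare lemma)."""
    choices = [lemma]
    for suffix in ("s", "ing", "ed"):
        if lemma.endswith("e") and suffix in ("ing", "ed"):
            cand = lemma[:-1] + suffix
        elif suffix == "s" and (lemma.endswith(("s", "x", "z", "ch", "sh"))):
            cand = lemma + "es"
        else:
            cand = lemma + suffix
        if normalize_token(cand) == lemma:
            choices.append(cand)
    return choices[int(rng.integers(len(choices)))]


def _make_transcript(pid, rng, checklist, produced, theta, cfg) -> Transcript:
    """Token stream for one speaker: produced checklist items embedded in
    phrases with function words, extra relevant words (so CIU > CWF),
    fillers, repetitions and occasional error tokens."""
    reserved = set()
    for it in checklist.items:
        reserved.add(it.lemma)
        reserved |= {normalize_token(s) for s in it.synonyms}
    extras_pool = [w for w in _EXTRA_RELEVANT if normalize_token(w) not in reserved]

    items = [checklist.items[j] for j in np.flatnonzero(produced)]
    perm = rng.permutation(len(items))
    items = [items[int(i)] for i in perm]
    lam = float(np.exp(1.0 + 0.5 * min(theta, 3.0)))
    n_extra = min(int(rng.poisson(lam)), len(extras_pool))
    extras = list(rng.choice(extras_pool, size=n_extra, replace=False)) if n_extra else []
    err_rate = 0.03 * (1.0 + max(0.0, -theta))

    content = [("item", it) for it in items] + [("extra", w) for w in extras]
    if content:
        perm = rng.permutation(len(content))
        content = [content[int(i)] for i in perm]

    tokens = []
    pos = 0
    phrase = 0
    def emit(surface, flags=frozenset()):
        nonlocal pos
        tokens.append(Token(position=pos, surface=surface, flags=flags, phrase_id=phrase))
        pos += 1

    per_phrase = 3
    for start in range(0, max(len(content), 1), per_phrase):
        chunk = content[start:start + per_phrase]
        emit(str(rng.choice(_FUNCTION_WORDS)))
        for kind, obj in chunk:
            if rng.random() < cfg.filler_rate:
                emit(str(rng.choice(_FILLERS)), frozenset({"filler"}))
            if rng.random() < err_rate:
                emit("xxx", frozenset({"unintelligible"}))
            if rng.random() < err_rate:
                emit(str(rng.choice(_OFF_TOPIC)), frozenset({"off_topic"}))
            if kind == "item":
                use_syn = obj.synonyms and rng.random() < 0.25
                base = str(rng.choice(sorted(obj.synonyms))) if use_syn else obj.lemma
                surface = _inflect(base, rng) if not use_syn else base
            else:
                surface = obj
            emit(surface)
            if rng.random() < cfg.repetition_rate:
                if rng.random() < 0.5:
                    emit(str(rng.choice(_FILLERS)), frozenset({"filler"}))
                emit(surface)
            if rng.random() < 0.6:
                emit(str(rng.choice(_FUNCTION_WORDS)))
        phrase += 1
    return Transcript(participant_id=pid, tokens=tuple(tokens))


def _aphasia_type(theta, rng) -> str:
    if theta < -0.9:
        return "broca" if rng.random() < 0.8 else "wernicke"
    if theta < -0.4:
        return "conduction" if rng.random() < 0.5 else "broca"
    return "anomic" if rng.random() < 0.9 else "conduction"


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort (checklist, lesions, abilities,
    transcripts, tract atlas, streamlines), byte-deterministic in the
    config."""
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2029]))
    checklist = generate_checklist(cfg.n_items, cfg.seed)
    b = item_difficulties(checklist, cfg.seed)
    shape = tuple(cfg.grid_shape)

    if cfg.critical_region is None:
        region = _default_critical_region(rng, shape)
    else:
        region = np.asarray(cfg.critical_region, int).reshape(-1, 3)
    if region.shape[0] == 0 and cfg.effect_beta != 0.0:
        raise ValueError("empty critical_region with nonzero effect_beta")
    region_flat = set(np.ravel_multi_index((region[:, 0], region[:, 1], region[:, 2]), shape)) \
        if region.shape[0] else set()

    n = cfg.n_participants
    center = np.array(shape) / 2.0
    volumes = []
    loads = np.zeros(n)
    max_size = int(np.prod(shape) * 0.15)
    for i in range(n):
        seed_vox = np.clip(np.round(center + rng.normal(0.0, np.array(shape) / 6.0)),
                           0, np.array(shape) - 1).astype(int)
        target = int(np.clip(rng.lognormal(np.log(400.0), 0.9), 20, max_size))
        blob = _grow_blob(rng, shape, seed_vox, target)
        mask = np.zeros(shape, dtype=np.uint8)
        mask[blob[:, 0], blob[:, 1], blob[:, 2]] = 1
        volumes.append(LesionVolume(data=mask, voxel_size_mm=(cfg.voxel_size_mm,) * 3,
                                    space_tag="synthetic"))
        if region_flat:
            flat = np.ravel_multi_index((blob[:, 0], blob[:, 1], blob[:, 2]), shape)
            loads[i] = len(region_flat.intersection(flat)) / len(region_flat)
    lesions = CohortLesions(subjects=tuple(f"sub{i:03d}" for i in range(n)),
                            volumes=tuple(volumes))

    theta = -cfg.effect_beta * loads + cfg.noise_sd * rng.standard_normal(n)

    transcripts = []
    types = []
    for i in range(n):
        produced = rng.random(len(checklist)) < _sigmoid(theta[i] - b)
        transcripts.append(_make_transcript(f"sub{i:03d}", rng, checklist,
                                            produced, theta[i], cfg))
        types.append(_aphasia_type(theta[i], rng))
    severity = np.clip(60.0 + 12.0 * theta, 0.0, 100.0)  # WAB-AQ-like scale

    atlas = _generate_tract_atlas(rng, shape, region)
    streamlines = generate_streamlines(atlas, n_per_tract=12,
                                       seed=int(rng.integers(2**31)), grid_shape=shape)
    return SyntheticCohort(checklist=checklist, transcripts=tuple(transcripts),
                           lesions=lesions, abilities=theta, tract_atlas=atlas,
                           streamlines=streamlines, true_difficulties=b,
                           critical_region=tuple(map(tuple, region.tolist())),
                           config=cfg, aphasia_type=tuple(types), severity=severity)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _generate_tract_atlas(rng, shape, critical_region) -> TractAtlas:
    """Eight named elongated tracts; the first (FAT) is routed through
    the critical region so tract-load analyses have a true positive."""
    tracts = {}
    for t, name in enumerate(_TRACT_NAMES):
        if name == "FAT" and len(critical_region):
            anchor = critical_region[len(critical_region) // 2]
        else:
            anchor = np.clip(np.round(np.array(shape) / 2.0 +
                                      rng.normal(0, np.array(shape) / 5.0)),
                             1, np.array(shape) - 2).astype(int)
        axis = int(rng.integers(3))
        length = max(4, int(min(shape) * 0.5))
        vox = set()
        p = np.array(anchor, dtype=int)
        for _ in range(length):
            for dx in (-1, 0, 1):
                q = p.copy()
                q[(axis + 1) % 3] = np.clip(q[(axis + 1) % 3] + dx, 0, shape[(axis + 1) % 3] - 1)
                vox.add(tuple(q))
            p[axis] = min(p[axis] + 1, shape[axis] - 1)
            if rng.random() < 0.3:
                j = (axis + 2) % 3
                p[j] = int(np.clip(p[j] + rng.integers(-1, 2), 0, shape[j] - 1))
        if name == "FAT" and len(critical_region):
            vox |= set(map(tuple, critical_region.tolist()))
        tracts[name] = np.array(sorted(vox), dtype=int)
    return TractAtlas(tracts=tracts, grid_shape=tuple(shape))


def generate_streamlines(tract_atlas: TractAtlas, n_per_tract: int = 12,
                         seed: int = 0, grid_shape=None) -> StreamlineSet:
    """Seeded random-walk voxel paths inside a 1-voxel dilation of each
    tract; every tract contributes n_per_tract streamlines."""
    if not tract_atlas.tracts:
        raise ValueError("empty tract atlas")
    shape = tuple(grid_shape or tract_atlas.grid_shape or ())
    if not shape:
        raise ValueError("grid shape required")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 727]))
    paths = []
    for name in sorted(tract_atlas.tracts):
        vox = tract_atlas.tracts[name]
        allowed = set()
        for v in vox:
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dz in (-1, 0, 1):
                        q = (v[0] + dx, v[1] + dy, v[2] + dz)
                        if all(0 <= c < s for c, s in zip(q, shape)):
                            allowed.add(q)
        for _ in range(n_per_tract):
            start = tuple(vox[int(rng.integers(len(vox)))])
            path = [start]
            cur = start
            target_len = max(3, len(vox) // 2)
            for _ in range(target_len):
                nbrs = []
                for axis in range(3):
                    for d in (-1, 1):
                        q = list(cur)
                        q[axis] += d
                        q = tuple(q)
                        if q in allowed:
                            nbrs.append(q)
                if not nbrs:
                    break
                cur = nbrs[int(rng.integers(len(nbrs)))]
                path.append(cur)
            paths.append(np.array(path, dtype=int))
    return StreamlineSet(streamlines=tuple(paths), grid_shape=shape)


def write_cohort(cohort: SyntheticCohort, outdir) -> dict:
    """Write all cohort artefacts (transcript TSVs, lesion NIfTIs,
    checklist JSON, streamlines/atlas JSON, behaviour seed columns) plus
    a manifest listing every output with its SHA-256."""
    out = Path(outdir)
    (out / "transcripts").mkdir(parents=True, exist_ok=True)
    (out / "lesions").mkdir(exist_ok=True)
    files = []
    for tr in cohort.transcripts:
        p = out / "transcripts" / f"{tr.participant_id}.tsv"
        write_transcript_tsv(tr, p)
        files.append(p)
    vs = cohort.lesions.volumes[0].voxel_size_mm if len(cohort.lesions) else (2.0, 2.0, 2.0)
    for sid, vol in zip(cohort.lesions.subjects, cohort.lesions.volumes):
        p = out / "lesions" / f"{sid}.nii.gz"
        save_volume_nifti(vol.data, p, vol.voxel_size_mm)
        files.append(p)
    write_checklist(cohort.checklist, out / "checklist.json")
    files.append(out / "checklist.json")
    save_streamlines_json(cohort.streamlines, out / "streamlines.json")
    files.append(out / "streamlines.json")
    save_tract_atlas_json(cohort.tract_atlas, out / "tract_atlas.json")
    files.append(out / "tract_atlas.json")
    behav = out / "behaviour.tsv"
    with open(behav, "w") as fh:
        fh.write("participant_id\taphasia_type\tseverity\tlesion_size_cc\n")
        sizes = cohort.lesions.lesion_size_cc if len(cohort.lesions) else []
        for i, tr in enumerate(cohort.transcripts):
            fh.write(f"{tr.participant_id}\t{cohort.aphasia_type[i]}\t"
                     f"{cohort.severity[i]:.4f}\t{sizes[i]:.4f}\n")
    files.append(behav)
    manifest = {
        "seed": cohort.config.seed,
        "n_participants": cohort.config.n_participants,
        "files": {str(p.relative_to(out)): _sha256(p) for p in sorted(files)},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
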