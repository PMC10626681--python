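"""Synthetic codon-usage tables, genes and benchmark scenarios.

The generator emulates the statistical structure a harmonization benchmark
assumes, without any downloads:

* **Tables** — per synonymous family, fractions are drawn from a Dirichlet
  with concentration ``alpha``, tilted toward G/C-ending codons by
  ``exp(gc3_bias)`` per G/C third base; amino-acid weights convert family
  fractions to frequencies per thousand.  Host presets lean AT
  (budding-yeast-like), mildly GC (enteric-bacterium-like) or strongly GC
  (streptomycete-like) purely through ``gc3_bias``.
* **Genes** — in-frame, start ATG, end with a stop, no internal stops;
  amino-acid composition is tilted so a target GC in 0.30–0.80 is reachable,
  then seeded synonymous swaps tune the gene's mean GC to ±0.02 of target.
* **Scenarios** — a default design of genes spanning the GC grid with
  per-gene source tables and enzyme-class labels, and a validation design
  (2 high-GC, 2 low-GC, 4 genes with inverted repeats of increasing length
  to grade secondary-structure content).

Everything is deterministic under its seed, and every emitted artifact
satisfies the corresponding container invariants.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .codon_tables import (
    ALL_CODONS,
    STANDARD_CODE,
    CodonUsageTable,
    GeneticCode,
    parse_cut,
    serialize_cut,
    translate,
)

__all__ = [
    "CutSpec",
    "GeneSpec",
    "GeneRecord",
    "ScenarioBundle",
    "generate_cut",
    "generate_gene",
    "generate_benchmark_set",
    "HOST_PRESETS",
    "write_bundle",
    "load_bundle",
]

# Average amino-acid composition of well-annotated proteomes (UniProtKB
# release statistics, rounded); used as the default weight vector.
DEFAULT_AA_WEIGHTS = {
    "A": 0.0826, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
    "Q": 0.0393, "E": 0.0672, "G": 0.0708, "H": 0.0228, "I": 0.0591,
    "L": 0.0965, "K": 0.0580, "M": 0.0241, "F": 0.0386, "P": 0.0474,
    "S": 0.0665, "T": 0.0536, "W": 0.0110, "Y": 0.0292, "V": 0.0686,
}
# one stop per ~330 codons, a typical CDS length
STOP_WEIGHT = 0.003

#: gc3_bias presets emulating the benchmark's heterologous hosts.
HOST_PRESETS = {
    "ecoli_like": 0.3,
    "cerevisiae_like": -0.8,
    "lividans_like": 2.5,
}


@dataclass(frozen=True)
class CutSpec:
    """Recipe for one synthetic codon usage table."""

    seed: int = 0
    alpha: float = 3.0
    gc3_bias: float = 0.0
    label: str = "synthetic"
    aa_weights: tuple | None = None  # ((aa, weight), ...) incl. '*', or None

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError(f"Dirichlet concentration must be > 0; got {self.alpha}")


@dataclass(frozen=True)
class GeneSpec:
    """Recipe for one synthetic gene."""

    seed: int = 0
    length: int = 300  # codons, start and stop included
    target_gc: float = 0.50
    enzyme_class: str = "EC1"
    gene_id: str = "gene"

    def __post_init__(self) -> None:
        if self.length < 3:
            raise ValueError("a gene needs at least start, one codon and stop")
        if not 0.0 < self.target_gc < 1.0:
            raise ValueError("target GC must be a fraction in (0, 1)")


@dataclass
class GeneRecord:
    """A generated gene plus its provenance."""

    gene_id: str
    sequence: str
    enzyme_class: str
    target_gc: float
    achieved_gc: float
    gc_on_target: bool
    source_label: str = ""

    def __post_init__(self) -> None:
        codons = [self.sequence[i:i + 3] for i in range(0, len(self.sequence), 3)]
        if len(self.sequence) % 3 != 0:
            raise ValueError("gene not in frame")
        if codons[0] != "ATG":
            raise ValueError("gene must start with ATG")
        aas = translate(self.sequence)
        if aas[-1] != "*" or "*" in aas[:-1]:
            raise ValueError("gene must end with its only stop codon")


def generate_cut(spec: CutSpec, code: GeneticCode = STANDARD_CODE) -> CodonUsageTable:
    """Draw a synthetic usage table from a CutSpec (deterministic under seed)."""
    rng = np.random.default_rng(spec.seed)
    weights = dict(spec.aa_weights) if spec.aa_weights else dict(DEFAULT_AA_WEIGHTS)
    weights.setdefault("*", STOP_WEIGHT)
    total_w = sum(weights.values())
    weights = {aa: w / total_w for aa, w in weights.items()}

    freqs: dict[str, float] = {}
    for aa, family in code.families.items():
        tilt = np.array([np.exp(spec.gc3_bias * (c[2] in "GC")) for c in family])
        fractions = rng.dirichlet(spec.alpha * tilt)
        for c, frac in zip(family, fractions):
            freqs[c] = float(frac * weights.get(aa, 0.0) * 1000.0)
    return CodonUsageTable(organism=spec.label, frequency_per_thousand=freqs,
                           counts=None, dialect="synthetic")


# ---------------------------------------------------------------------------
# gene generation
# ---------------------------------------------------------------------------

def _gc_count(codon: str) -> int:
    return sum(b in "GC" for b in codon)


def _aa_weight_tilt(base: dict[str, float], gamma: float,
                    gc_mid: dict[str, float]) -> dict[str, float]:
    w = {aa: base[aa] * np.exp(gamma * (gc_mid[aa] - 0.5)) for aa in base}
    total = sum(w.values())
    return {aa: v / total for aa, v in w.items()}


def generate_gene(spec: GeneSpec, cut: CodonUsageTable,
                  code: GeneticCode = STANDARD_CODE) -> GeneRecord:
    """Generate one gene: ATG + drawn amino acids + stop, GC-tuned.

    The amino-acid distribution starts from the source table's implied
    composition and is exponentially tilted so the target GC is reachable;
    codons are then sampled per family fraction and refined by seeded
    synonymous swaps until the gene's mean GC is within ±0.02 of target (or
    no swap improves it further, in which case the best achieved GC is
    reported, never silently accepted).
    """
    rng = np.random.default_rng(spec.seed)
    fams = code.families
    aa_list = [aa for aa in fams if aa not in ("*", "M")]

    # family fractions from the source table (uniform fallback for zero families)
    fam_fracs: dict[str, np.ndarray] = {}
    for aa, family in fams.items():
        f = np.array([cut.frequency_per_thousand[c] for c in family])
        fam_fracs[aa] = f / f.sum() if f.sum() > 0 else np.full(len(family), 1 / len(family))

    base_w = {aa: sum(cut.frequency_per_thousand[c] for c in fams[aa])
              for aa in aa_list}
    tot = sum(base_w.values())
    base_w = ({aa: w / tot for aa, w in base_w.items()} if tot > 0
              else {aa: 1 / len(aa_list) for aa in aa_list})
    # midpoint of each family's achievable per-nucleotide GC
    gc_mid = {
        aa: (min(_gc_count(c) for c in fams[aa]) + max(_gc_count(c) for c in fams[aa])) / 6.0
        for aa in aa_list
    }

    # tilt the composition so the target is inside the achievable band
    lo_g, hi_g = -14.0, 14.0
    gamma = 0.0
    for _ in range(40):
        gamma = 0.5 * (lo_g + hi_g)
        w = _aa_weight_tilt(base_w, gamma, gc_mid)
        mid = sum(w[aa] * gc_mid[aa] for aa in aa_list)
        if mid < spec.target_gc:
            lo_g = gamma
        else:
            hi_g = gamma
    weights = _aa_weight_tilt(base_w, gamma, gc_mid)

    n_middle = spec.length - 2
    aas = rng.choice(aa_list, size=n_middle, p=[weights[a] for a in aa_list])
    stop_family = list(fams["*"])
    stop = stop_family[rng.choice(len(stop_family), p=fam_fracs["*"])]
    codons = ["ATG"]
    for aa in aas:
        family = fams[aa]
        codons.append(family[rng.choice(len(family), p=fam_fracs[aa])])
    codons.append(stop)

    # seeded synonymous swaps toward the GC target
    gc_codon = np.array([_gc_count(c) for c in codons], dtype=float)
    total_nt = 3 * len(codons)
    target_count = spec.target_gc * total_nt
    tol_count = 0.02 * total_nt

    def _current() -> float:
        return gc_codon.sum()

    for _ in range(20):  # passes
        need = target_count - _current()
        if abs(need) <= tol_count:
            break
        improved = False
        for p in rng.permutation(len(codons)):
            need = target_count - _current()
            if abs(need) <= tol_count:
                break
            family = fams[code.amino_acid(codons[p])]
            cur_gc = _gc_count(codons[p])
            best_c, best_step = None, 0
            for c in family:
                step = _gc_count(c) - cur_gc
                if need > 0 and step > best_step:
                    best_c, best_step = c, step
                elif need < 0 and step < best_step:
                    best_c, best_step = c, step
            if best_c is not None and abs(best_step) <= abs(need) + tol_count:
                codons[p] = best_c
                gc_codon[p] = _gc_count(best_c)
                improved = True
        if not improved:
            break

    achieved = _current() / total_nt
    return GeneRecord(
        gene_id=spec.gene_id,
        sequence="".join(codons),
        enzyme_class=spec.enzyme_class,
        target_gc=spec.target_gc,
        achieved_gc=float(achieved),
        gc_on_target=bool(abs(achieved - spec.target_gc) <= 0.02 + 1e-12),
        source_label=cut.organism,
    )


def _embed_inverted_repeat(record: GeneRecord, stem_len_nt: int, rng,
                           code: GeneticCode = STANDARD_CODE) -> GeneRecord:
    """Overwrite a mid-gene block with a stem–loop to raise structure content.

    The stem of ``stem_len_nt`` plus a 4-nt loop replaces in-frame codons in
    the middle of the gene; drawn stems are rejected until the edit
    introduces no internal stop.
    """
    if stem_len_nt == 0:
        return record
    comp = str.maketrans("ACGT", "TGCA")
    seq = record.sequence
    insert_len = 2 * stem_len_nt + 4
    n_codons_repl = -(-insert_len // 3)  # ceil
    pad = n_codons_repl * 3 - insert_len
    start_codon_idx = (len(seq) // 3 - n_codons_repl) // 2
    start_nt = start_codon_idx * 3
    for _ in range(200):
        stem = "".join(rng.choice(list("ACGT"), size=stem_len_nt))
        loop = "GAAA"
        block = stem + loop + stem.translate(comp)[::-1]
        block += "".join(rng.choice(list("AT"), size=pad))
        cand = seq[:start_nt] + block + seq[start_nt + len(block):]
        aas = translate(cand, code)
        if "*" not in aas[:-1] and aas[-1] == "*":
            from .usage_metrics import gc_content

            _, gc = gc_content(cand, window=None)
            return GeneRecord(
                gene_id=record.gene_id, sequence=cand,
                enzyme_class=record.enzyme_class, target_gc=record.target_gc,
                achieved_gc=gc, gc_on_target=record.gc_on_target,
                source_label=record.source_label,
            )
    raise RuntimeError(f"could not embed a {stem_len_nt}-nt stem without stops")


# ---------------------------------------------------------------------------
# benchmark scenarios
# ---------------------------------------------------------------------------

@dataclass
class ScenarioBundle:
    """A full benchmark scenario: genes, per-gene source tables, host tables."""

    genes: list[GeneRecord]
    source_cuts: dict[str, CodonUsageTable]  # gene_id -> table
    host_cuts: dict[str, CodonUsageTable]  # host label -> table
    manifest: pd.DataFrame
    design: str = "default"
    master_seed: int = 0
    meta: dict = field(default_factory=dict)


def _child_seed(master: int, tag: str) -> int:
    """Deterministic per-artifact seed below 2**31 (stable across processes)."""
    digest = zlib.crc32(tag.encode())
    return int(np.random.SeedSequence([master, digest]).generate_state(1)[0]
               % (2 ** 31))


def generate_benchmark_set(n_genes: int = 27, hosts=("ecoli_like", "cerevisiae_like"),
                           design: str = "default", master_seed: int = 0,
                           length_range: tuple[int, int] = (100, 600),
                           gc_range: tuple[float, float] = (0.30, 0.80),
                           code: GeneticCode = STANDARD_CODE) -> ScenarioBundle:
    """Generate a benchmark scenario.

    ``design="default"``: ``n_genes`` genes spanning the GC grid, lengths
    drawn from ``length_range``, alternating enzyme classes, each with its
    own GC-matched source table.  ``design="validation"``: the 8-gene preset
    (2 high-GC, 2 low-GC, 4 with inverted repeats of 0/12/24/36 nt).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not hosts:
        raise ValueError("at least one host is required")
    rng = np.random.default_rng(master_seed)

    host_cuts = {}
    for host in hosts:
        beta = HOST_PRESETS.get(host, 0.0)
        host_cuts[host] = generate_cut(CutSpec(
            seed=_child_seed(master_seed, f"host:{host}"),
            gc3_bias=beta, label=host,
        ), code)

    genes: list[GeneRecord] = []
    source_cuts: dict[str, CodonUsageTable] = {}

    if design == "default":
        targets = np.linspace(gc_range[0], gc_range[1], n_genes)
        lengths = rng.integers(length_range[0], length_range[1] + 1, size=n_genes)
        for i, (target, length) in enumerate(zip(targets, lengths)):
            gid = f"gene{i:03d}"
            src_spec = CutSpec(
                seed=_child_seed(master_seed, f"src:{gid}"),
                gc3_bias=float(6.0 * (target - 0.5)),
                label=f"source_{gid}",
            )
            src = generate_cut(src_spec, code)
            rec = generate_gene(GeneSpec(
                seed=_child_seed(master_seed, f"gene:{gid}"),
                length=int(length), target_gc=float(target),
                enzyme_class="EC1" if i % 2 == 0 else "EC2", gene_id=gid,
            ), src, code)
            genes.append(rec)
            source_cuts[gid] = src
    elif design == "validation":
        specs = [
            ("vhigh0", 0.75, 0), ("vhigh1", 0.72, 0),
            ("vlow0", 0.32, 0), ("vlow1", 0.35, 0),
            ("vstruct0", 0.50, 0), ("vstruct1", 0.50, 12),
            ("vstruct2", 0.50, 24), ("vstruct3", 0.50, 36),
        ]
        for i, (gid, target, stem) in enumerate(specs):
            src_spec = CutSpec(
                seed=_child_seed(master_seed, f"src:{gid}"),
                gc3_bias=float(6.0 * (target - 0.5)), label=f"source_{gid}",
            )
            src = generate_cut(src_spec, code)
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            rec = generate_gene(GeneSpec(
                seed=_child_seed(master_seed, f"gene:{gid}"), length=length,
                target_gc=target, enzyme_class="EC1" if i % 2 == 0 else "EC2",
                gene_id=gid,
            ), src, code)
            rec = _embed_inverted_repeat(
                rec, stem, np.random.default_rng(_child_seed(master_seed, f"stem:{gid}")),
                code)
            genes.append(rec)
            source_cuts[gid] = src
    else:
        raise ValueError(f"unknown design {design!r}")

    manifest = pd.DataFrame([
        dict(gene_id=g.gene_id, length_codons=len(g.sequence) // 3,
             target_gc=g.target_gc, achieved_gc=g.achieved_gc,
             gc_on_target=g.gc_on_target, enzyme_class=g.enzyme_class,
             source_cut=g.source_label)
        for g in genes
    ])
    return ScenarioBundle(
        genes=genes, source_cuts=source_cuts, host_cuts=host_cuts,
        manifest=manifest, design=design, master_seed=master_seed,
        meta={"hosts": list(hosts), "n_genes": n_genes},
    )


# ---------------------------------------------------------------------------
# disk round-trip
# ---------------------------------------------------------------------------

def write_bundle(bundle: ScenarioBundle, outdir) -> Path:
    """Write a scenario to disk: FASTA genes, Kazusa-dialect tables, manifest."""
    out = Path(outdir)
    (out / "cuts").mkdir(parents=True, exist_ok=True)
    with open(out / "genes.fasta", "w") as fh:
        for g in bundle.genes:
            fh.write(f">{g.gene_id} enzyme_class={g.enzyme_class} "
                     f"source={g.source_label}\n{g.sequence}\n")
    for gid, cut in bundle.source_cuts.items():
        (out / "cuts" / f"{cut.organism}.kazusa.txt").write_text(
            serialize_cut(cut, "kazusa"))
    for host, cut in bundle.host_cuts.items():
        (out / "cuts" / f"{host}.kazusa.txt").write_text(
            serialize_cut(cut, "kazusa"))
    bundle.manifest.to_csv(out / "manifest.csv", index=False)
    (out / "scenario.json").write_text(json.dumps({
        "design": bundle.design, "master_seed": bundle.master_seed,
        "hosts": list(bundle.host_cuts), **bundle.meta,
    }, indent=2, sort_keys=True) + "\n")
    return out


def load_bundle(indir) -> ScenarioBundle:
    """Reload a scenario written by :func:`write_bundle`."""
    from Bio import SeqIO

    indir = Path(indir)
    meta = json.loads((indir / "scenario.json").read_text())
    manifest = pd.read_csv(indir / "manifest.csv")
    genes = []
    attrs = manifest.set_index("gene_id")
    for rec in SeqIO.parse(str(indir / "genes.fasta"), "fasta"):
        row = attrs.loc[rec.id]
        genes.append(GeneRecord(
            gene_id=rec.id, sequence=str(rec.seq),
            enzyme_class=row["enzyme_class"], target_gc=float(row["target_gc"]),
            achieved_gc=float(row["achieved_gc"]),
            gc_on_target=bool(row["gc_on_target"]),
            source_label=row["source_cut"],
        ))
    source_cuts = {}
    for g in genes:
        path = indir / "cuts" / f"{g.source_label}.kazusa.txt"
        source_cuts[g.gene_id] = parse_cut(path.read_text(), "kazusa",
                                           organism=g.source_label)
    host_cuts = {}
    for host in meta["hosts"]:
        path = indir / "cuts" / f"{host}.kazusa.txt"
        host_cuts[host] = parse_cut(path.read_text(), "kazusa", organism=host)
    return ScenarioBundle(
        genes=genes, source_cuts=source_cuts, host_cuts=host_cuts,
        manifest=manifest, design=meta["design"],
        master_seed=int(meta["master_seed"]),
        meta={k: meta[k] for k in meta if k not in ("design", "master_seed")},
    )
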