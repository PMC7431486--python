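#!/usr/bin/env python
"""Karyotype 21 heat-shocked isolates and cluster their aneuploidies.

Implants the 34-event aneuploidy tally (26 trisomy, 4 UPD, 2 monosomy,
1 pentasomy, 1 tetrasomy, spread over 11 aneuploid isolates) into 21
synthetic whole-genome isolates, calls per-chromosome karyotypes from the
simulated arrays, estimates the aneuploidy rate against the spontaneous
baseline (31 events over ~311,000 divisions), and two-way-clusters the
isolate x chromosome copy-state matrix.

Writes: results/karyotypes.tsv, results/aneuploidy_rates.tsv,
results/karyotype_clustering.txt
"""

import sys
from pathlib import Path

import pandas as pd

import lohscan as L
from lohscan import rosters
from lohscan.io import RunConfig, write_karyotypes, write_tsv
from lohscan.pipeline import process_isolate
from lohscan.stats import cluster_karyotypes, dendrogram_text, encode_karyotypes

SEED = 1
DIVISIONS = 25
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cfg = RunConfig(seed=SEED, divisions_per_isolate=DIVISIONS, outdir=str(OUT))
    genome = L.build_default_genome()
    markers = L.build_marker_map(genome, "whole_genome", seed=SEED)
    isolates = [f"JP{i}" for i in range(1, 22)]

    roster = rosters.heat_aneuploidy_roster(genome, seed=SEED)
    gt = L.implant_events(L.GenotypeMatrix.baseline(markers, isolates), roster)
    sig = L.simulate_signals(gt, noise=L.NoiseModel(seed=SEED))
    karyotypes = [process_isolate(sig[iso], markers, iso).karyotype for iso in isolates]
    write_karyotypes(karyotypes, OUT / "karyotypes.tsv", cfg)

    counts: dict[str, int] = {}
    for k in karyotypes:
        for label, _ in k.non_normal().values():
            counts[label] = counts.get(label, 0) + 1
    n_events = sum(counts.values())
    n_aneuploid = sum(1 for k in karyotypes if k.non_normal())
    print(f"whole-chromosome events called in {len(isolates)} isolates: {counts}")
    print(f"{n_aneuploid} of {len(isolates)} isolates carry at least one event")

    heat = L.event_rate(n_events, len(isolates), DIVISIONS)
    spont = L.event_rate(*rosters.SPONTANEOUS_ANEUPLOIDY)
    rates = pd.DataFrame(
        [
            {"condition": "heat_shock", "n_events": n_events, "rate": float(heat.rate),
             "rate_2sf": heat.rounded(2)},
            {"condition": "spontaneous", "n_events": spont.n_events,
             "rate": float(spont.rate), "rate_1sf": spont.rounded(1)},
        ]
    )
    write_tsv(rates, OUT / "aneuploidy_rates.tsv", cfg)
    print(f"aneuploidy rate: {float(heat.rate):.4f} (~{heat.rounded(2)}) "
          f"events/genome/division; spontaneous ~{spont.rounded(1):.0e}")
    print(f"elevation: ~{L.fold_elevation(heat, spont):.0f}x "
          "(two orders of magnitude)")

    mat, iso_ids, cols = encode_karyotypes(karyotypes)
    clust = cluster_karyotypes(mat)
    ordered = [iso_ids[i] for i in clust["row_order"]]
    text = dendrogram_text(clust["row_linkage"], iso_ids)
    (OUT / "karyotype_clustering.txt").write_text(
        "# isolate dendrogram (complete linkage, Euclidean)\n"
        + text + "\n# leaf order: " + " ".join(ordered) + "\n"
    )
    print("isolates with similar aneuploidies cluster adjacently; leaf order:")
    print(" ", " ".join(ordered))


if __name__ == "__main__":
    sys.exit(main())
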