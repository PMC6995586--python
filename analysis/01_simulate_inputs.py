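"""Generate the synthetic input bundle used by the downstream analyses.

Writes, under results/fixtures/:
  * an alignment Gibbs-sampled from a Potts model with 10 planted couplings
    (L=50, q=8, M=4000, coupling 1.5) plus 10% near-duplicate rows;
  * a 60-residue toy helix structure (PDB) and a metal-bridged version with
    a pseudo-atom cross-linking residues 20-28;
  * a 6-predictor disorder score table with two planted disordered stretches;
  * ground_truth.json recording what was planted.
"""

import json
import sys
from pathlib import Path

from sodnet import synthetic

OUT = Path(__file__).resolve().parent.parent / "results" / "fixtures"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 7


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    pairs = synthetic.plant_random_pairs(50, 10, 1.5, seed=SEED)
    spec = synthetic.PottsSpec(
        L=50, q=8, M=4000, n_sweeps=50, planted_pairs=pairs,
        duplication_fraction=0.1, seed=SEED,
    )
    truth = synthetic.write_fixture_bundle(
        OUT, spec, chain_n=60, chain_geometry="helix",
        disordered_ranges=[(15, 30), (45, 55)],
    )
    coords, seq = synthetic.make_toy_chain(60, "helix", seed=SEED)
    linked = synthetic.add_crosslink(coords, [19, 23, 27])  # 0-based: residues 20-28
    synthetic.write_ca_pdb(linked, seq + "G", OUT / "chain_crosslinked.pdb")
    print(f"wrote fixture bundle to {OUT}")
    print(json.dumps(truth, indent=2, sort_keys=True))


if __name__ == "__main__":
    main()
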