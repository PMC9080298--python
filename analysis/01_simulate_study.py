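"""Generate the synthetic two-block profiling study at its default conditions.

12 tumor cell lines x 4 drug classes x 3 drugs x treated/control x 3
replicates (864 biological samples), pooled QCs every 6 injections, 300 RP +
200 HILIC features with 12 planted marker metabolites per class.

Writes inputs (peak tables, metadata, marker manifest) under results/inputs/.
"""

from pathlib import Path

import moaprofile as mp
from moaprofile import io as ptio

OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = mp.SyntheticConfig(seed=SEED)
    rp, hi, meta, manifest = mp.generate_study(cfg)
    ptio.write_peak_table(rp, OUT / "rp.tsv")
    ptio.write_peak_table(hi, OUT / "hilic.tsv")
    ptio.write_sample_meta(meta, OUT / "meta.tsv")
    manifest.to_csv(OUT / "manifest_markers.tsv", sep="\t", index=False)
    n_bio = (meta["condition"] != "qc").sum()
    n_qc = (meta["condition"] == "qc").sum()
    print(f"simulated {n_bio} biological samples + {n_qc} QC injections, "
          f"{rp.n_features} RP + {hi.n_features} HILIC features")
    print(f"planted {len(manifest)} marker features "
          f"({cfg.markers_per_class} per class); wrote {OUT}")


if __name__ == "__main__":
    main()
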