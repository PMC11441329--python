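"""Group comparisons on the quantification tables.

Per-synapse STED peak levels: Kruskal-Wallis across the four conditions
followed by Dunn's comparisons against the channel-null background (cTKO).
Somatic HA means: Wilcoxon-free two-group check is not needed here; the
per-cell table is compared with Kruskal-Wallis as well (two groups reduce
to a rank-sum comparison).

Run after 02/04:  python analysis/05_group_stats.py
"""

from pathlib import Path

import pandas as pd

from synquant.stats import kruskal_dunn

ROOT = Path(__file__).resolve().parents[1]
OUT_DIR = ROOT / "results" / "stats"


def main():
    OUT_DIR.mkdir(parents=True, exist_ok=True)

    peaks = pd.read_csv(ROOT / "results" / "profiles" / "peaks.csv")
    groups = {c: g["peak_value"].to_numpy()
              for c, g in peaks.groupby("condition", sort=False)}
    res = kruskal_dunn(groups, reference="cTKO")
    post = res.posthoc.copy()
    post.insert(0, "kw_p", res.p_value)
    post.insert(0, "kw_H", res.statistic)
    post.to_csv(OUT_DIR / "peaks_kw_dunn.csv", index=False, float_format="%.6g")
    print(f"STED peaks (n/synapses per group: "
          f"{ {k: len(v) for k, v in groups.items()} })")
    print(f"  Kruskal-Wallis H={res.statistic:.2f}, p={res.p_value:.3g}")
    for _, r in post.iterrows():
        flag = "*" if r["reject"] else "ns"
        print(f"  Dunn {r['group_b']} vs {r['group_a']}: "
              f"z={r['z']:.2f}, adj p={r['p_adjusted']:.3g} [{flag}]")

    somata = pd.read_csv(ROOT / "results" / "somata" / "soma_means.csv")
    sgroups = {c: g["mean_ha"].to_numpy()
               for c, g in somata.groupby("condition", sort=False)}
    sres = kruskal_dunn(sgroups)
    spost = sres.posthoc.copy()
    spost.insert(0, "kw_p", sres.p_value)
    spost.insert(0, "kw_H", sres.statistic)
    spost.to_csv(OUT_DIR / "soma_kw.csv", index=False, float_format="%.6g")
    print(f"somatic HA: H={sres.statistic:.2f}, p={sres.p_value:.3g}")
    print(f"-> {OUT_DIR}")


if __name__ == "__main__":
    main()
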