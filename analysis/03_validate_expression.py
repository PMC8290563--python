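"""Expression-phase validation of the shortlisted pairs.

Re-runs the screen to obtain the shortlist, then computes the validation
statistics on the simulated animal study: 2^(-ddCT) fold changes with
one-way ANOVA per target, Pearson correlation per pair within each group,
ROC discrimination of the top lncRNA for diseased-group membership,
HOMA-IR and tolerance-test AUC summaries.  Tables land in
results/validation/.
"""

import argparse
import importlib.util
import sys
from pathlib import Path

from hmlnet.pipeline import run_screen, run_validation

ROOT = Path(__file__).resolve().parents[1]

# sibling numbered script (not an importable module name)
_spec = importlib.util.spec_from_file_location(
    "screen_driver", Path(__file__).parent / "02_screen_network.py"
)
_screen_driver = importlib.util.module_from_spec(_spec)
sys.modules["screen_driver"] = _screen_driver
_spec.loader.exec_module(_screen_driver)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--fixtures", default=str(ROOT / "scratch" / "fixtures"))
    parser.add_argument("--outdir", default=str(ROOT / "results" / "validation"))
    args = parser.parse_args()

    fixture_dir = Path(args.fixtures)
    truth = _screen_driver.ensure_fixtures(fixture_dir, args.seed)
    cfg = _screen_driver.screen_config(fixture_dir, Path(args.outdir), args.seed)
    screen = run_screen(cfg, write=False)
    short = {c.mrna_id for c in screen.shortlist}
    pairs = [p for p in screen.pairs if p.mrna_id in short]
    report = run_validation(cfg, shortlist_pairs=pairs)

    anova = report["anova"]
    print("per-target ANOVA across groups (fold scale):")
    print(anova[["target", "F", "p", "direction_hf_sed"]].to_string(index=False))
    corr = report["correlations"]
    hf = corr[corr["group"] == "HF-Sed"]
    print("\npair correlations in the sedentary high-fat group (n = 6):")
    print(hf[["mrna_id", "lncrna_id", "r", "p"]].to_string(index=False))
    print("\nplanted correlations:")
    for (m, l), rho in sorted(truth.planted_rho.items()):
        print(f"  {m} -- {l}: rho = {rho}")
    if not report["roc"].empty:
        roc = report["roc"].iloc[0]
        print(f"\nROC of {roc['target']} fold change vs diseased-group label: "
              f"AUC = {roc['auc']:.3f} [{roc['ci_low']:.3f}, {roc['ci_high']:.3f}]")
    pheno = report["phenotypes"]
    if not pheno.empty:
        pheno = pheno.assign(group=pheno["sample"].str.rsplit("_", n=1).str[0])
        print("\nphenotype summaries by group:")
        print(
            pheno.groupby("group")[["homa_ir", "tolerance_auc"]]
            .mean()
            .to_string(float_format="%.1f")
        )
    print(f"\ntables written to {args.outdir}")


if __name__ == "__main__":
    main()
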