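"""Motif-constrained search of the synthetic spectra with target-decoy FDR.

Searches the simulated MGF against the simulated chain database (plus
reversed decoys), keeps the best PSM per spectrum, and filters at 1% q-value.
Reports how many accepted PSMs match the generating peptidoform.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from colptm.chain_model import read_fasta
from colptm.motif_search import fdr_filter, read_mgf, search_spectra, write_psm_tsv

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "synthetic_dataset"
OUT = ROOT / "results" / "psms.tsv"


def main():
    chains = read_fasta(DATA / "chains.fasta")
    spectra = read_mgf(DATA / "spectra.mgf")
    psms = search_spectra(spectra, chains)
    accepted = fdr_filter(psms, 0.01)
    targets = [p for p in accepted if not p.is_decoy]
    truth = pd.read_csv(DATA / "spectrum_truth.tsv", sep="\t")
    by_id = dict(zip(truth["spectrum_id"], truth["peptidoform"]))
    correct = sum(1 for p in targets
                  if p.peptidoform.peptidoform_str() == by_id.get(p.spectrum_id))
    write_psm_tsv(accepted, OUT, header_comment="synthetic search, q<=0.01")
    print(f"{len(spectra)} spectra -> {len(accepted)} PSMs at 1% FDR "
          f"({len(targets)} targets, {correct} match the generating peptidoform)")
    print(f"PSM table -> {OUT}")


if __name__ == "__main__":
    main()
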