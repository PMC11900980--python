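"""Infer the net predicted direction of three epigenetic marks.

Bookkeeping: a miRNA going up pushes its target down; a mark follows its
writers and opposes its erasers. Each interaction contributes one signed
unit, so net = (writer-down - writer-up) + (eraser-up - eraser-down).
"""

from epimir import (
    consensus_interactions,
    filter_de,
    infer_all_marks,
    load_paper_fixture,
)

fixture = load_paper_fixture()
interactions = consensus_interactions(
    filter_de(list(fixture.de_records)),
    fixture.predictions_a,
    fixture.predictions_b,
    fixture.catalog,
)

for report in infer_all_marks(interactions, fixture.catalog):
    print(f"{report.mark}:")
    print(f"  writer interactions: {report.n_writer_up} up / {report.n_writer_down} down")
    print(f"  eraser interactions: {report.n_eraser_up} up / {report.n_eraser_down} down")
    print(f"  net score {report.net_score:+d} over {report.n_contributing} interactions "
          f"-> predicted {report.direction}")
# Positive net score = the mark is predicted to rise in the disease state.
# "slightly" flags a net within 20% of the contributing interaction count.
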