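"""Build the relative-benefit comparator network for one setting.

Each graded trial becomes a directed edge comparator -> experimental arm
weighted by its final grade; arm labels are normalized so spelling
variants merge into one node.
"""

from pathlib import Path

from esmo_mcbs import Setting, build_network, export_network, grade_all, load_corpus

entries = load_corpus()
records = [e.record for e in entries]
results = grade_all(records)

for setting in (Setting.PLATINUM_SENSITIVE, Setting.PLATINUM_RESISTANT):
    net = build_network(records, results, setting)
    print(f"{setting.value}: {len(net.nodes)} arms, {len(net.edges)} graded comparisons")
    for edge in net.edges:
        print(f"  {edge.source} -> {edge.target}  (grade {edge.grade}, {edge.trial_id})")
    out = Path(f"network_{setting.value}.dot")
    export_network(net, out, format="dot")
    print(f"  wrote {out} (edge weight = final MCBS grade; a higher grade means "
          "more benefit over that particular comparator — grades earned against "
          "different comparators are not directly comparable)")
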