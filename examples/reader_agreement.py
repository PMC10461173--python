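"""Quantify inter-reader variability from two reader match tables.

Two readers matched the same scan pair (3 lesions on each scan) and filled
the two-column workbook: positive indices in both columns mark a match, a
zero marks "no counterpart on that scan".  The readers disagree on lesion 1:
reader A says it disappeared and a new lesion appeared nearby, reader B says
the two are the same lesion.  That single judgement call changes three edges
of the match graph.
"""

import tempfile
from pathlib import Path

from lesionmatch import compare_graphs, read_match_table

workdir = Path(tempfile.mkdtemp())
n1, n2 = {1, 2, 3}, {1, 2, 3}

(workdir / "reader_a.csv").write_text("1,0\n0,1\n2,2\n3,3\n")
(workdir / "reader_b.csv").write_text("1,1\n2,2\n3,3\n")

g_a = read_match_table(workdir / "reader_a.csv", n1, n2)
g_b = read_match_table(workdir / "reader_b.csv", n1, n2)
print("reader A edges:", sorted(map(str, g_a.edges)))
print("reader B edges:", sorted(map(str, g_b.edges)))

rep = compare_graphs(g_a, g_b)
print(f"precision={rep.precision:.3f} recall={rep.recall:.3f} "
      f"f1={rep.f1:.3f} n_differences={rep.n_differences}")
print("The disappeared+new reading versus the matched reading differ in "
      "3 edges; the two shared matches give precision 2/4 and recall 2/3.")
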