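{
 "comment": "Schematic element library and pattern catalog (synthetic stand-in shaped like the published element-pattern diagrams). Real-data runs should supply a library built from reference alignments.",
 "elements": [
  {
   "index": 0,
   "name": "e1",
   "consensus": "ACATCGGGACACTCCATAACGGCGGCCATGTTAGTAATCCCGCACACGTATTTGGTCTGTAAACATGGGCTT",
   "min_len": 72,
   "max_len": 72
  },
  {
   "index": 1,
   "name": "e2",
   "consensus": "GAATATAGAGAAAGGCAGCTAGCGTTTAGTAAAGGCAGACAGTCGCCACGCGGATGCCTGGCCAGCTGCATCCCGGGAGATCACCTGTATCATATCCACCAC",
   "min_len": 102,
   "max_len": 102
  },
  {
   "index": 2,
   "name": "e3",
   "consensus": "ACAAGGACTGAATACGCGTTCCCGCCCCTGAGCAAAACGATCACCCGCCCATTATTGGTGAAGTCTTTAGTCGAGCGGAGCCGTTCGGCCATAAATGTATTGCACTCCTTAAGGCCGTTG",
   "min_len": 120,
   "max_len": 120
  },
  {
   "index": 3,
   "name": "e4",
   "consensus": "GGGCCCTACTGCCAGGTTGAGTCAGACAACATGGAACTACCCGGTATGCGATTGCTTGAGCACGGTGGATGCCGACATGTTTACTGTCAATGGTGTTGCGTCATTCACACGCGATGCTGC",
   "min_len": 120,
   "max_len": 120
  },
  {
   "index": 4,
   "name": "e5",
   "consensus": "CACAGTGCCGCTTCGTATGTGGACTCACAGCAGAAGAGTAACCGATTATCACTGCGAAAAGAAGGGTCGCCCAAACTTTGCGCTCTCCATGGAAATACTGCAAAGACA",
   "min_len": 108,
   "max_len": 108
  },
  {
   "index": 5,
   "name": "e6",
   "consensus": "AATCAATGCATCTTCCGGCGCCGTCGTCATCGCCCTTACAGTCTATGCAGCCCA",
   "min_len": 54,
   "max_len": 54
  },
  {
   "index": 6,
   "name": "e7",
   "consensus": "TCGAGCTTGGGACACCGGCGCCGTGGACATATTCCCCTTCACATGAGAGAGCAGTATTCTGTTACATGTTTCTTT",
   "min_len": 75,
   "max_len": 75
  },
  {
   "index": 7,
   "name": "e8",
   "consensus": "GGTCCTATCGGCAGGTTAGTCCAGTCCGATCACCTCAGCACTTGCCGGGTGGACTCCTGTAGTAGATCGGGGTTACCGGGAAACACATATTTCTCTGTTGAAAATAGTGTA",
   "min_len": 111,
   "max_len": 111
  },
  {
   "index": 8,
   "name": "e9",
   "consensus": "AGCATCAGTTCGGGTAGCCAAAATGATCCTGTCCGTGGCAAGGTAGCGAGTGTAACGAACGCCACCCAGCGGGAACTG",
   "min_len": 78,
   "max_len": 78
  },
  {
   "index": 9,
   "name": "e10",
   "consensus": "ATTGCCTCTACAGCTTCTTTACGCCCGCGCGCAGGCCAAAGGCACGATAAATATCCTTCAGGAGGAGAATTACCGCGAAACATTATAGCGGATGACTGGGGC",
   "min_len": 102,
   "max_len": 102
  },
  {
   "index": 10,
   "name": "e11",
   "consensus": "GGAACTGCGGCCTACCATCTCCATTGCTTCCTGACTAGCACAATTAAGATCTGTCTCCCGCCCTCGGATGTAGGTGACAACCACCTCATC",
   "min_len": 90,
   "max_len": 90
  },
  {
   "index": 11,
   "name": "e12",
   "consensus": "TTGAGAAGCGATTGGCACGCACGTGCACTGCGGGTATTAGGCCGTTGCGCTAACCCCCAT",
   "min_len": 60,
   "max_len": 60
  },
  {
   "index": 12,
   "name": "e13",
   "consensus": "ATACCGATCTCCCGGCCTAACCTTCCGAAGTATTTGATCGATCGTACTCTTCCTAAATCTACGGAGTTGCAGTGCTCACTCGCCGCCTTAGCCTATGAAGGACGTAGA",
   "min_len": 108,
   "max_len": 108
  },
  {
   "index": 13,
   "name": "e14",
   "consensus": "TGGATTGCCATTGCCAACACCAACAGTGACAGTCGAGGCAATGCTACGCGAGTAATCATATCAGCCTTGGGAGTCCAATTATCCTCCGTGCGA",
   "min_len": 93,
   "max_len": 93
  },
  {
   "index": 14,
   "name": "e15",
   "consensus": "GTATGTCCTCTTGCGTCTACGGCCCGTAGACCACTGACTAGCACGACAATCTTG",
   "min_len": 54,
   "max_len": 54
  }
 ],
 "patterns": {
  "A3": [
   false,
   true,
   true,
   true,
   false,
   true,
   false,
   true,
   true,
   true,
   true,
   true,
   false,
   true,
   true
  ],
  "C2": [
   false,
   false,
   true,
   false,
   false,
   true,
   false,
   true,
   true,
   true,
   true,
   false,
   false,
   true,
   true
  ],
  "D1": [
   true,
   true,
   false,
   true,
   false,
   true,
   true,
   false,
   false,
   true,
   true,
   false,
   false,
   true,
   true
  ],
  "C3": [
   true,
   false,
   true,
   true,
   true,
   false,
   false,
   true,
   true,
   true,
   true,
   false,
   true,
   false,
   true
  ],
  "D5": [
   true,
   true,
   true,
   false,
   true,
   true,
   true,
   true,
   true,
   false,
   false,
   true,
   true,
   false,
   true
  ],
  "B3": [
   true,
   false,
   true,
   true,
   true,
   true,
   true,
   true,
   false,
   false,
   false,
   true,
   true,
   true,
   true
  ],
  "E2": [
   true,
   true,
   false,
   false,
   false,
   true,
   true,
   true,
   false,
   false,
   true,
   true,
   true,
   false,
   true
  ],
  "01": [
   false,
   true,
   true,
   true,
   false,
   false,
   true,
   true,
   true,
   false,
   true,
   true,
   false,
   false,
   true
  ],
  "02": [
   true,
   true,
   false,
   true,
   true,
   false,
   true,
   true,
   true,
   true,
   false,
   true,
   false,
   true,
   true
  ],
  "A4": [
   false,
   true,
   false,
   true,
   true,
   true,
   true,
   false,
   false,
   true,
   true,
   true,
   true,
   false,
   true
  ],
  "G2": [
   false,
   false,
   false,
   false,
   true,
   false,
   true,
   true,
   true,
   false,
   true,
   true,
   true,
   true,
   true
  ],
  "D2": [
   false,
   false,
   false,
   true,
   true,
   true,
   false,
   true,
   false,
   true,
   true,
   true,
   true,
   true,
   true
  ]
 }
}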