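{
  "_comment": "NCBI genetic code tables used in metazoan mitochondrial genomes, transcribed from the NCBI Taxonomy genetic-code registry. 'aa' lists the translation of the 64 codons in the standard order (first base T,C,A,G slowest; third base T,C,A,G fastest); '*' marks stop. 'starts' lists the initiation codons defined by the table.",
  "tables": {
    "2": {
      "name": "Vertebrate Mitochondrial",
      "aa": "FFLLSSSSYY**CCWWLLLLPPPPHHQQRRRRIIMMTTTTNNKKSS**VVVVAAAADDEEGGGG",
      "starts": ["ATT", "ATC", "ATA", "ATG", "GTG"]
    },
    "4": {
      "name": "Mold/Protozoan/Coelenterate Mitochondrial",
      "aa": "FFLLSSSSYY**CCWWLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG",
      "starts": ["TTA", "TTG", "CTG", "ATT", "ATC", "ATA", "ATG", "GTG"]
    },
    "5": {
      "name": "Invertebrate Mitochondrial",
      "aa": "FFLLSSSSYY**CCWWLLLLPPPPHHQQRRRRIIMMTTTTNNKKSSSSVVVVAAAADDEEGGGG",
      "starts": ["TTG", "ATT", "ATC", "ATA", "ATG", "GTG"]
    },
    "9": {
      "name": "Echinoderm/Flatworm Mitochondrial",
      "aa": "FFLLSSSSYY**CCWWLLLLPPPPHHQQRRRRIIIMTTTTNNNKSSSSVVVVAAAADDEEGGGG",
      "starts": ["ATG", "GTG"]
    },
    "13": {
      "name": "Ascidian Mitochondrial",
      "aa": "FFLLSSSSYY**CCWWLLLLPPPPHHQQRRRRIIMMTTTTNNKKSSGGVVVVAAAADDEEGGGG",
      "starts": ["TTG", "ATA", "ATG", "GTG"]
    },
    "14": {
      "name": "Alternative Flatworm Mitochondrial",
      "aa": "FFLLSSSSYYY*CCWWLLLLPPPPHHQQRRRRIIIMTTTTNNNKSSSSVVVVAAAADDEEGGGG",
      "starts": ["ATG"]
    },
    "24": {
      "name": "Pterobranchia Mitochondrial",
      "aa": "FFLLSSSSYY**CCWWLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSSKVVVVAAAADDEEGGGG",
      "starts": ["TTG", "CTG", "ATT", "ATG", "GTG"]
    }
  }
}
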