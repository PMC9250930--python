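7aabd92fdd518fbd2ed42302ac634a4c815fddd2340a8d8f3562e9c58e86fd6e  table2_catalogue.tsv
3732ebb89ce6190ddb78f02eba1ebf4e4aac782457adfd6f52cb9d5a9a36ef6b  table4_proximity.tsv
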