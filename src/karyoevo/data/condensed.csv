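taxon,genus,x,nor_pairs_raw,provenance
"Bokermannohyla spp.",Bokermannohyla,12,11,discussion:nor-location
"Dendropsophini",,12,11,discussion:basic-number
"Hylini",,12,11,discussion:basic-number
"Lophyohylini",,12,11,discussion:basic-number
"Pelodryadinae",,13,,discussion:basic-number
"Phyllomedusinae",,13,,discussion:basic-number
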