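coalpop export
199/200
417/418
464/465
EV1Pm
EV37Mn
EV94Mn
EV96Mn
GATA028
TAA031
GATA053
GATA417
POP
ASHW001 , 010009 017013 008013 008008 010017 014018 011011 017017 009014 013015 014011
ASHW002 , 015008 013009 008015 008009 017015 008013 011015 010008 009009 008008 014014
ASHW003 , 013008 009015 008013 013008 010013 008018 011010 014017 013014 009015 014015
ASHW004 , 008015 017015 013013 013009 010021 018008 011011 018008 014009 015009 008014
ASHW005 , 015013 011014 015008 008009 015020 008015 014011 017009 014014 015015 008008
ASHW006 , 008013 014017 008008 009008 010013 013018 011010 012017 011013 012013 014014
ASHW007 , 008014 011009 008013 008009 015013 014013 015011 009018 011009 016014 009008
ASHW008 , 014014 017017 008014 013009 014015 011008 014015 008008 009014 009013 011008
ASHW009 , 014008 009009 008012 013008 009011 015009 013011 010014 013009 015013 015014
ASHW010 , 009013 014016 013008 008008 009014 008011 011014 018017 013013 013014 015014
ASHW011 , 010015 014009 012008 013008 015010 009013 013014 018009 014013 013014 008014
ASHW012 , 015008 009013 012015 013013 010017 008008 011013 009011 009014 008015 015014
ASHW013 , 013014 017009 012012 008008 019013 011013 011011 012017 009014 015015 008014
ASHW014 , 008009 009013 013013 013009 018010 008013 013010 000000 014014 015013 014014
ASHW015 , 014015 009009 013008 008008 016015 015008 014010 009016 014009 014013 014014
ASHW016 , 009009 016017 013013 013013 014015 011018 012012 018008 009013 008008 011009
ASHW017 , 015013 011009 014013 013009 009010 014008 011012 014017 009009 009015 015008
ASHW018 , 013009 009011 008008 008008 010015 018008 014011 017017 009013 013008 015008
ASHW019 , 008008 014013 012015 009013 016015 015010 013013 009009 014009 008013 009014
ASHW020 , 013008 011014 013015 013008 017009 015018 011015 010018 009009 009014 008009
ASHW021 , 015008 015014 013013 013009 010019 018015 011012 009012 014013 009013 014009
ASHW022 , 013010 011014 013013 013009 013015 008018 011015 016008 009014 008013 014009
ASHW023 , 009015 014009 012015 013008 014015 008008 013011 017010 014014 013013 014009
ASHW024 , 014014 009013 008008 013009 009017 013014 012010 018017 014013 008015 008008
ASHW025 , 008010 014014 013013 009008 010015 008008 011015 018008 011014 014008 014009
ASHW026 , 013013 011014 013013 013008 013014 009015 011011 017017 013009 008009 009015
ASHW027 , 008008 017011 013008 013013 015013 008018 012014 018012 009009 013009 015014
ASHW028 , 015008 017009 013008 013009 009021 008013 015015 009010 014014 009014 008008
ASHW029 , 015015 017017 008012 013009 014016 018008 014011 008018 009009 008009 014009
ASHW030 , 010013 009009 012008 013013 015018 011008 012014 014009 014009 015008 015009
ASHW031 , 015014 013009 013013 013013 015010 014015 011011 018014 014009 009015 015014
ASHW032 , 015015 017017 012013 013008 015010 008015 011011 009018 009009 015013 008014
ASHW033 , 014015 017014 008008 008013 019015 008010 010011 009009 009014 016009 014008
ASHW034 , 015008 013017 013013 008009 020015 008008 011015 008014 009014 013009 009009
ASHW035 , 015008 014009 013008 008013 010015 009014 011013 008008 009014 013009 009015
ASHW036 , 013010 017011 013013 013008 017016 008011 012011 012018 009009 014009 014014
ASHW037 , 008015 016013 008013 009009 011015 013015 011011 008016 014009 015015 015009
ASHW038 , 008008 009009 012015 013009 020015 008008 011011 009017 014009 015015 014008
ASHW039 , 009015 014009 013008 013013 013020 008011 011011 008008 013014 009008 014009
ASHW040 , 009015 009011 015008 013009 019019 018013 011011 018010 009009 015013 014008
ASHW041 , 008013 016014 008008 013009 010010 013008 011011 008008 013013 008015 008014
ASHW042 , 015014 009015 013013 008013 017010 011008 011010 009009 009009 009015 014008
ASHW043 , 015013 013017 013008 008013 009015 008018 010015 010012 014009 016013 014014
ASHW044 , 015015 016017 013008 013008 017015 008008 011011 008009 014009 015009 015015
ASHW045 , 015015 009009 008014 008013 011015 008013 013012 008018 009014 009014 009008
ASHW046 , 014010 009011 013015 013008 009015 008014 011013 009012 014013 013008 009009
ASHW047 , 013008 013009 013014 013008 019009 014010 015011 009008 009009 009008 014008
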