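species,breeding,post_breeding,nonbreeding,pre_breeding
american_avocet,May-Jun,Jul-Nov,Dec-Jan,Feb-Apr
black_necked_stilt,Jun,Jul-Nov,Dec-Feb,Mar-May
canvasback,Jun-Aug,Sep-Nov,Dec-Jan,Feb-May
cinnamon_teal,May-Jun,Jul-Nov,Dec-Jan,Feb-Apr
northern_pintail,Jun-Jul,Aug-Nov,Dec-Jan,Feb-May
wilsons_phalarope,Jun,Jul-Oct,Nov-Feb,Mar-May
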