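female_form	male_form	match_kind
she	he	exact
hers	his	exact
herself	himself	exact
her	his	pos_disambiguated
her	him	pos_disambiguated
woman	man	exact
women	men	exact
lady	gentleman	exact
ladies	gentlemen	exact
female	male	exact
females	males	exact
girl	boy	exact
girls	boys	exact
mother	father	exact
mothers	fathers	exact
grandmother	grandfather	exact
grandmothers	grandfathers	exact
wife	husband	exact
wives	husbands	exact
daughter	son	exact
daughters	sons	exact
sister	brother	exact
sisters	brothers	exact
aunt	uncle	exact
aunts	uncles	exact
niece	nephew	exact
nieces	nephews	exact
widow	widower	exact
widows	widowers	exact
mrs	mr	title
ms	mr	title
miss	mr	title
madam	sir	exact
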