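group_code,label,polarity,include_keywords,exclude_keywords
C25a,Fresh fruit,healthy,fresh fruit;fruit,juice;juices
C25b,Cooked vegetables,healthy,cooked vegetables,
C25c,Raw vegetables or salad,healthy,raw vegetables;salad,
C25d,Full fat cheese/yogurt/fromage frais,healthy,full fat cheese;full fat yogurt;fromage frais,
C25e,Low fat cheese/low fat yogurt,healthy,low fat cheese;low fat yogurt,
C25f,Full cream milk or full cream milk products,healthy,full cream milk;full cream milk products,meat;fish
C25g,Skimmed/semi-skimmed milk or milk products,healthy,skimmed milk;semi skimmed milk;milk products,meat;fish
C25h,"Water (tap, still, sparkling)",healthy,water;tap water;still water;sparkling water,
C25i,"Hamburger, hot dog, sausage, meat pie",unhealthy,hamburger;hot dog;sausage;meat pie,products
C25j,Hot chips or french fries,unhealthy,hot chips;french fries;chips,
C25k,Crisps or savor snacks,unhealthy,crisps;savor snacks;savoury snacks,
C25l,"Biscuits, doughnuts, cake, pie or chocolate",unhealthy,biscuits;doughnuts;cake;pie;chocolate,
C25m,Sweets,unhealthy,sweets,
C25n,Fizzy drinks/minerals/cordial/squash (diet),unhealthy,diet fizzy drinks;diet minerals;diet cordial;diet squash,
C25o,Fizzy drinks/minerals/cordials/squash (not diet),unhealthy,fizzy drinks;minerals;cordials;squash,diet
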