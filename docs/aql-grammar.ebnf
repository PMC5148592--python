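(* Supported AQL subset. Keywords are case-insensitive; identifiers and
   archetype ids are case-sensitive. *)

query     = "SELECT" selitem { "," selitem }
            "FROM" "EHR" IDENT { contains }
            [ "WHERE" condition ] ;

selitem   = IDENT [ pathtail ] [ "AS" IDENT ] ;

contains  = "CONTAINS" RMTYPE IDENT [ "[" CLASSID "]" ] ;
            (* without the bracketed archetype id the class pattern is
               the wildcard "*"; an id without a version component
               matches any version of that concept *)

pathtail  = "/" step { "/" step } ;
step      = NAME [ "[" ATCODE "]" ] ;

condition = or_expr ;
or_expr   = and_expr { "OR" and_expr } ;
and_expr  = not_expr { "AND" not_expr } ;
not_expr  = "NOT" not_expr | "(" condition ")" | predicate ;

predicate = IDENT [ pathtail ] comp literal
          | IDENT [ pathtail ] ( "MATCHES" | "IN" )
            "{" literal { "," literal } "}"
          | "EXISTS" IDENT [ pathtail ] ;

comp      = "=" | "!=" | ">" | ">=" | "<" | "<=" ;
literal   = NUMBER | STRING | "TRUE" | "FALSE" ;

(* ORDER BY and TIMEWINDOW are recognized and rejected as unsupported. *)
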